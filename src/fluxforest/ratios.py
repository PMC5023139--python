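"""Flux-ratio definitions: user formulas over reaction fluxes.

A ratio is numerator/denominator where each side is a signed linear
combination of reaction fluxes, each term taken on the net, forward, or
backward flux of a reaction.  For every feasible flux map the value must
lie in [0, 1] (the numerator is a sub-flux of the denominator pool).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import RatioError
from .network import MetabolicNetwork

__all__ = ["RatioTerm", "RatioDefinition", "compute_ratio"]

_DIRECTIONS = ("net", "fwd", "bwd")


@dataclass(frozen=True)
class RatioTerm:
    reaction: str
    coef: float = 1.0
    direction: str = "net"

    def __post_init__(self) -> None:
        if self.direction not in _DIRECTIONS:
            raise RatioError(
                f"term '{self.reaction}': direction must be one of {_DIRECTIONS}"
            )


@dataclass
class RatioDefinition:
    """numerator / denominator, both lists of :class:`RatioTerm`."""

    name: str
    numerator: list[RatioTerm]
    denominator: list[RatioTerm]

    @classmethod
    def from_dict(cls, d: dict) -> "RatioDefinition":
        def terms(side):
            out = []
            for t in d[side]:
                if isinstance(t, str):
                    out.append(RatioTerm(t))
                else:
                    out.append(
                        RatioTerm(
                            t["reaction"],
                            float(t.get("coef", 1.0)),
                            t.get("direction", "net"),
                        )
                    )
            return out

        return cls(d["name"], terms("numerator"), terms("denominator"))

    def to_dict(self) -> dict:
        def side(terms):
            return [
                {"reaction": t.reaction, "coef": t.coef, "direction": t.direction}
                for t in terms
            ]

        return {
            "name": self.name,
            "numerator": side(self.numerator),
            "denominator": side(self.denominator),
        }

    def validate(self, network: MetabolicNetwork) -> None:
        for t in self.numerator + self.denominator:
            network.reaction_index(t.reaction)  # raises on unknown id

    # -- evaluation ---------------------------------------------------------
    def _side_value(self, terms, network, net, exch):
        total = np.zeros(np.shape(net)[:-1] or ())
        for t in terms:
            j = network.reaction_index(t.reaction)
            v = np.asarray(net)[..., j]
            if t.direction == "fwd":
                e = 0.0 if exch is None else np.asarray(exch)[..., j]
                v = e + np.maximum(v, 0.0)
            elif t.direction == "bwd":
                e = 0.0 if exch is None else np.asarray(exch)[..., j]
                v = e + np.maximum(-v, 0.0)
            total = total + t.coef * v
        return total

    def value(self, network, net, exch=None, clip: bool = True):
        """Ratio value(s) for net flux vector(s) (last axis = reactions).

        Raises :class:`RatioError` when the denominator vanishes or the
        value falls outside [0, 1] beyond tolerance 1e-9; otherwise values
        are clipped into [0, 1].
        """
        num = self._side_value(self.numerator, network, net, exch)
        den = self._side_value(self.denominator, network, net, exch)
        den_arr = np.asarray(den, dtype=float)
        if np.any(den_arr <= 1e-12):
            raise RatioError(
                f"ratio '{self.name}': denominator <= 1e-12 (undefined ratio)"
            )
        r = np.asarray(num, dtype=float) / den_arr
        if np.any(r < -1e-9) or np.any(r > 1 + 1e-9):
            raise RatioError(
                f"ratio '{self.name}': value outside [0,1] "
                f"(min {np.min(r):.3g}, max {np.max(r):.3g})"
            )
        if clip:
            r = np.clip(r, 0.0, 1.0)
        return float(r) if np.ndim(r) == 0 else r

    # -- linear form for sampling constraints -------------------------------
    def linear_coefficients(self, network: MetabolicNetwork):
        """(num_coeffs, den_coeffs) over reactions, for net-flux-linear ratios.

        Only available when every term has direction ``net`` (the form used
        to impose ratio-bin constraints during flux sampling).
        """
        n = len(network.reactions)
        num = np.zeros(n)
        den = np.zeros(n)
        for terms, vec in ((self.numerator, num), (self.denominator, den)):
            for t in terms:
                if t.direction != "net":
                    raise RatioError(
                        f"ratio '{self.name}': term '{t.reaction}' uses direction "
                        f"'{t.direction}'; ratio constraints need net-linear terms"
                    )
                vec[network.reaction_index(t.reaction)] += t.coef
        return num, den


def compute_ratio(ratio_def: RatioDefinition, flux_state) -> float:
    """Evaluate a ratio on a :class:`~fluxforest.sampling.FluxState`."""
    return ratio_def.value(
        flux_state.network, flux_state.net, exch=flux_state.exch, clip=True
    )
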