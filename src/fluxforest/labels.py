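"""Substrate 13C-labeling specifications (tracer mixtures).

A tracer mixture describes, per substrate, a set of components with molar
fractions and per-carbon 13C enrichment probabilities.  Positions not
explicitly enriched carry the natural 13C abundance (default 1.07% per
carbon).  Spec dictionaries (YAML/JSON-friendly) look like::

    substrate: glc.ext
    natural_abundance: 0.0107
    components:
      - fraction: 0.2
        uniform: true            # [U-13C]
      - fraction: 0.8
        positions: []            # naturally labeled

    # or positionally labeled, 1-based carbon positions:
      - fraction: 1.0
        positions: [1]           # [1-13C]
        purity: 1.0
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TracerError

NATURAL_ABUNDANCE_13C = 0.0107

__all__ = [
    "SubstrateLabelMixture",
    "parse_label",
    "mdv_from_enrichment",
    "NATURAL_ABUNDANCE_13C",
]


@dataclass
class SubstrateLabelMixture:
    """Mixture of positionally enriched tracers, possibly for several substrates.

    ``components`` maps substrate name -> list of (fraction, enrichment
    vector); the enrichment vector holds the per-carbon 13C probability.
    """

    components: dict[str, list[tuple[float, np.ndarray]]]
    natural_abundance: float = NATURAL_ABUNDANCE_13C
    name: str = ""

    def validate(self) -> None:
        for sub, comps in self.components.items():
            if not comps:
                raise TracerError(f"substrate '{sub}': no mixture components")
            total = sum(f for f, _ in comps)
            if abs(total - 1.0) > 1e-9:
                raise TracerError(
                    f"substrate '{sub}': component fractions sum to {total!r}, not 1"
                )
            ncar = {len(e) for _, e in comps}
            if len(ncar) != 1:
                raise TracerError(f"substrate '{sub}': inconsistent carbon counts")
            for f, e in comps:
                if f < -1e-12 or f > 1 + 1e-12:
                    raise TracerError(f"substrate '{sub}': fraction {f} outside [0,1]")
                if np.any(e < -1e-12) or np.any(e > 1 + 1e-12):
                    raise TracerError(f"substrate '{sub}': enrichment outside [0,1]")

    def enrichment_components(
        self, substrate: str, n_carbons: int
    ) -> list[tuple[float, np.ndarray]]:
        """Components for ``substrate``; unspecified substrates get natural label."""
        if substrate in self.components:
            comps = self.components[substrate]
            if len(comps[0][1]) != n_carbons:
                raise TracerError(
                    f"substrate '{substrate}': tracer defines "
                    f"{len(comps[0][1])} carbons, network has {n_carbons}"
                )
            return comps
        return [(1.0, np.full(n_carbons, self.natural_abundance))]

    def emu_mdv(self, substrate: str, atoms: tuple[int, ...]) -> np.ndarray:
        """Mass distribution of the substrate fragment at 0-based ``atoms``.

        Within a component carbons are independent Bernoulli draws; the
        fragment MDV is the convolution over positions, mixture-weighted.
        """
        n = max(atoms) + 1
        comps = self.enrichment_components(substrate, max(n, self._ncar(substrate, n)))
        out = np.zeros(len(atoms) + 1)
        for frac, enr in comps:
            mdv = np.array([1.0])
            for pos in atoms:
                p = enr[pos]
                mdv = np.convolve(mdv, [1.0 - p, p])
            out += frac * mdv
        return out

    def _ncar(self, substrate: str, default: int) -> int:
        if substrate in self.components:
            return len(self.components[substrate][0][1])
        return default


def mdv_from_enrichment(enrichment: np.ndarray) -> np.ndarray:
    """Full-molecule MDV of independent per-carbon enrichment probabilities."""
    mdv = np.array([1.0])
    for p in np.asarray(enrichment, dtype=float):
        mdv = np.convolve(mdv, [1.0 - p, p])
    return mdv


def _component_enrichment(comp: dict, n_carbons: int, nat: float) -> np.ndarray:
    enr = np.full(n_carbons, nat, dtype=float)
    purity = float(comp.get("purity", 1.0))
    if comp.get("uniform", False):
        enr[:] = purity
    for pos in comp.get("positions", []):
        if not (1 <= int(pos) <= n_carbons):
            raise TracerError(
                f"labeled position {pos} outside carbon range 1..{n_carbons}"
            )
        enr[int(pos) - 1] = purity
    for pos, p in dict(comp.get("enrichment", {})).items():
        if not (1 <= int(pos) <= n_carbons):
            raise TracerError(
                f"enriched position {pos} outside carbon range 1..{n_carbons}"
            )
        enr[int(pos) - 1] = float(p)
    return enr


def parse_label(spec: dict, n_carbons: dict[str, int] | int) -> SubstrateLabelMixture:
    """Build a validated :class:`SubstrateLabelMixture` from a spec dict.

    ``spec`` is either a single-substrate dict (keys ``substrate``,
    ``components``) or ``{"substrates": [<single-substrate dict>, ...]}``.
    ``n_carbons`` gives the carbon count per substrate (or one count if an
    int).  Carbon positions in the spec are 1-based.
    """
    nat = float(spec.get("natural_abundance", NATURAL_ABUNDANCE_13C))
    entries = spec.get("substrates", [spec])
    components: dict[str, list[tuple[float, np.ndarray]]] = {}
    for entry in entries:
        sub = entry.get("substrate")
        if not sub:
            raise TracerError("tracer spec entry lacks a 'substrate' key")
        if isinstance(n_carbons, int):
            nc = n_carbons
        else:
            if sub not in n_carbons:
                raise TracerError(f"unknown substrate '{sub}' in tracer spec")
            nc = n_carbons[sub]
        comps = [
            (float(c.get("fraction", 1.0)), _component_enrichment(c, nc, nat))
            for c in entry.get("components", [])
        ]
        if not comps:
            raise TracerError(f"substrate '{sub}': no mixture components")
        components[sub] = comps
    mix = SubstrateLabelMixture(
        components, natural_abundance=nat, name=str(spec.get("name", ""))
    )
    mix.validate()
    return mix
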