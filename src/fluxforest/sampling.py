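"""Steady-state flux sampling.

Generates cohorts of flux maps spanning the feasible space of a network:

1. an initial net-flux solution minimizing the sum of squared fluxes under
   stoichiometric constraints, flux bounds, and a fixed major uptake flux;
2. Monte-Carlo sampling by moving in the null space of the stoichiometric
   matrix (Gaussian perturbations with rejection, falling back to a
   hit-and-run walk over the constraint polytope when acceptance is poor);
3. per-reaction exchange fluxes for reversible reactions drawn uniformly
   up to a user bound relative to the net flux;
4. stratified sampling over flux-ratio bins so the ratio of interest is
   uniformly represented across its feasible range.

Default bounds: reversible reactions in [-100, 100], irreversible in
[0, 100], major uptake fixed to 10 (arbitrary units).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .errors import InfeasibleError, SamplingError
from .network import MetabolicNetwork
from .ratios import RatioDefinition

__all__ = [
    "FluxState",
    "FluxCohort",
    "find_uptake_reaction",
    "flux_bounds",
    "initial_flux",
    "sample_net_fluxes",
    "assign_exchange",
    "stratified_cohort",
    "multi_ratio_cohort",
    "ratio_values",
    "infeasible_bin_indices",
]

DEFAULT_FLUX_BOUND = 100.0
DEFAULT_UPTAKE = 10.0
STOICH_TOL = 1e-6


@dataclass
class FluxState:
    """Net/exchange/forward/backward fluxes for one sampled flux map."""

    network: MetabolicNetwork
    net: np.ndarray
    exch: np.ndarray

    @property
    def fwd(self) -> np.ndarray:
        return self.exch + np.maximum(self.net, 0.0)

    @property
    def bwd(self) -> np.ndarray:
        return self.exch + np.maximum(-self.net, 0.0)

    def validate(self) -> None:
        S = self.network.stoichiometric_matrix()
        resid = np.abs(S @ self.net).max() if S.size else 0.0
        if resid > STOICH_TOL:
            raise SamplingError(f"stoichiometric residual {resid:.2e} > {STOICH_TOL}")
        rev = self.network.reversible_mask
        if np.any(self.exch[~rev] != 0.0):
            raise SamplingError("irreversible reaction has nonzero exchange flux")
        if np.any(self.net[~rev] < -1e-9):
            raise SamplingError("irreversible reaction has negative net flux")
        if np.any(self.exch < 0):
            raise SamplingError("negative exchange flux")


@dataclass
class FluxCohort:
    """A cohort of flux maps with per-sample ratio labels."""

    network: MetabolicNetwork
    net: np.ndarray            # (n_samples, n_reactions)
    exch: np.ndarray           # (n_samples, n_reactions)
    ratios: dict[str, np.ndarray] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.net.shape[0]

    @property
    def fwd(self) -> np.ndarray:
        return self.exch + np.maximum(self.net, 0.0)

    @property
    def bwd(self) -> np.ndarray:
        return self.exch + np.maximum(-self.net, 0.0)

    def state(self, i: int) -> FluxState:
        return FluxState(self.network, self.net[i], self.exch[i])

    def to_frame(self):
        import pandas as pd

        cols = {}
        for j, rid in enumerate(self.network.reaction_ids):
            cols[f"net.{rid}"] = self.net[:, j]
        for j, rid in enumerate(self.network.reaction_ids):
            if self.network.reactions[j].reversible:
                cols[f"exch.{rid}"] = self.exch[:, j]
        for name, vals in self.ratios.items():
            cols[f"ratio.{name}"] = vals
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Constraint assembly


def find_uptake_reaction(network: MetabolicNetwork) -> str:
    """First reaction consuming a declared substrate (the major uptake)."""
    for r in network.reactions:
        if any(o.metabolite in network.substrates for o in r.reactants):
            return r.id
    raise InfeasibleError("no reaction consumes a declared substrate")


def flux_bounds(network: MetabolicNetwork, flux_bound: float = DEFAULT_FLUX_BOUND):
    rev = network.reversible_mask
    lb = np.where(rev, -flux_bound, 0.0)
    ub = np.full(len(network.reactions), flux_bound)
    return lb, ub


def output_constraints(
    network: MetabolicNetwork, min_flux: float
) -> list[tuple[np.ndarray, float]]:
    """Inequality rows forcing each biomass-precursor output above ``min_flux``.

    Applies to sink reactions of multi-carbon metabolites (every biomass
    precursor and secreted product must be produced at some small rate, so
    every measured pool has throughput); 1-carbon sinks (CO2 venting) are
    left free.
    """
    rows = []
    carbons = network.metabolites
    for j, r in enumerate(network.reactions):
        if r.is_sink and any(carbons[o.metabolite] > 1 for o in r.reactants):
            c = np.zeros(len(network.reactions))
            c[j] = 1.0
            rows.append((c, float(min_flux)))
    return rows


def _ratio_inequalities(network, ratio_constraint, den_min):
    """Rows (c, b) meaning c @ v >= b for a ratio-bin constraint."""
    if ratio_constraint is None:
        return []
    ratio_def, lo, hi = ratio_constraint
    num, den = ratio_def.linear_coefficients(network)
    # require a strictly interior sliver at internal bin edges, so bins that
    # are feasible only on a measure-zero boundary face (e.g. a ratio with a
    # structural maximum at the edge) register as infeasible instead of
    # emitting boundary samples that belong to the neighboring bin
    margin = 1e-6
    lo_eff = lo + margin if lo > 0.0 else 0.0
    hi_eff = hi - margin if hi < 1.0 else 1.0
    rows = [
        (num - lo_eff * den, 0.0),   # ratio >= lo
        (hi_eff * den - num, 0.0),   # ratio <= hi
        (num, 0.0),                  # numerator nonnegative
        (den - num, 0.0),            # denominator >= numerator
        (den, den_min),              # pool actually carries flux
    ]
    return rows


# ---------------------------------------------------------------------------
# Initial solution (minimum-norm QP)


def initial_flux(
    network: MetabolicNetwork,
    extra_constraints=None,
    *,
    uptake_reaction: str | None = None,
    uptake_value: float = DEFAULT_UPTAKE,
    flux_bound: float = DEFAULT_FLUX_BOUND,
    ratio_constraint=None,
    output_min: float | None = None,
) -> np.ndarray:
    """Minimum sum-of-squares net-flux vector satisfying all constraints.

    ``extra_constraints`` is a list of (coeffs, lower) rows meaning
    ``coeffs @ v >= lower``.  ``ratio_constraint`` is (RatioDefinition,
    lo, hi) restricting the ratio to a segment.
    """
    m = len(network.reactions)
    S = network.stoichiometric_matrix()
    lb, ub = flux_bounds(network, flux_bound)
    if uptake_reaction is None:
        uptake_reaction = find_uptake_reaction(network)
    ju = network.reaction_index(uptake_reaction)
    lb = lb.copy()
    ub = ub.copy()
    lb[ju] = ub[ju] = uptake_value

    if output_min is None:
        output_min = 0.01 * abs(uptake_value)
    ineq = list(extra_constraints or [])
    ineq += output_constraints(network, output_min)
    ineq += _ratio_inequalities(
        network, ratio_constraint, den_min=1e-3 * abs(uptake_value)
    )

    # cheap LP feasibility probe (also a good warm start for the QP)
    A_ub = b_ub = None
    if ineq:
        A_ub = -np.array([c for c, _ in ineq])
        b_ub = -np.array([b for _, b in ineq])
    lp = optimize.linprog(
        np.zeros(m),
        A_eq=S if S.size else None,
        b_eq=np.zeros(S.shape[0]) if S.size else None,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    if lp.status == 2:  # proven infeasible
        raise InfeasibleError(
            "no feasible flux vector under stoichiometry, bounds"
            + (", output and ratio constraints" if ineq else "")
        )
    x0 = lp.x if (lp.status == 0 and lp.x is not None) else None
    if x0 is None:
        x0 = np.zeros(m)
        x0[ju] = uptake_value
    constraints = [optimize.LinearConstraint(S, 0.0, 0.0)]
    if ineq:
        A = np.array([c for c, _ in ineq])
        blo = np.array([b for _, b in ineq])
        constraints.append(optimize.LinearConstraint(A, blo, np.inf))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # optimizer chatter on tight polytopes
        res = optimize.minimize(
            lambda v: 0.5 * float(v @ v),
            x0,
            jac=lambda v: v,
            bounds=optimize.Bounds(lb, ub),
            constraints=constraints,
            method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-12},
        )
        v = res.x
        ok = res.success and _feasible(v, S, lb, ub, ineq)
        if not ok:
            res = optimize.minimize(
                lambda v: 0.5 * float(v @ v),
                x0,
                jac=lambda v: v,
                hess=lambda v: np.eye(m),
                bounds=optimize.Bounds(lb, ub),
                constraints=constraints,
                method="trust-constr",
                options={"maxiter": 2000, "gtol": 1e-10, "xtol": 1e-12},
            )
            v = res.x
        if not _feasible(v, S, lb, ub, ineq):
            raise InfeasibleError(
                "no feasible flux vector: "
                + "; ".join(_violations(network, v, S, lb, ub, ineq))
            )
    # snap tiny violations onto the box
    return np.clip(v, lb, ub)


def _feasible(v, S, lb, ub, ineq, tol=1e-6):
    if S.size and np.abs(S @ v).max() > tol:
        return False
    if np.any(v < lb - tol) or np.any(v > ub + tol):
        return False
    for c, b in ineq:
        if c @ v < b - tol:
            return False
    return True


def _violations(network, v, S, lb, ub, ineq, tol=1e-6):
    out = []
    if S.size:
        resid = np.abs(S @ v)
        for i, m in enumerate(network.balanced_metabolites):
            if resid[i] > tol:
                out.append(f"mass balance of '{m}' (residual {resid[i]:.2e})")
    for j, rid in enumerate(network.reaction_ids):
        if v[j] < lb[j] - tol or v[j] > ub[j] + tol:
            out.append(f"bounds of reaction '{rid}'")
    for k, (c, b) in enumerate(ineq):
        if c @ v < b - tol:
            out.append(f"inequality constraint #{k} (value {c @ v:.3g} < {b:.3g})")
    return out or ["optimizer did not converge"]


# ---------------------------------------------------------------------------
# Null-space Monte-Carlo sampling


class _Polytope:
    """Feasible set in null-space coordinates: {a : G a <= h}, v = v0 + N a."""

    def __init__(self, network, v0, *, uptake_reaction, flux_bound, ineq):
        S = network.stoichiometric_matrix()
        ju = network.reaction_index(uptake_reaction)
        e = np.zeros((1, len(v0)))
        e[0, ju] = 1.0
        A_eq = np.vstack([S, e]) if S.size else e
        self.N = linalg.null_space(A_eq)
        self.v0 = v0
        lb, ub = flux_bounds(network, flux_bound)
        lb = lb.copy()
        ub = ub.copy()
        lb[ju] = ub[ju] = v0[ju]
        G_rows, h_rows = [], []
        if self.N.shape[1]:
            G_rows.append(self.N)
            h_rows.append(ub - v0)
            G_rows.append(-self.N)
            h_rows.append(v0 - lb)
            for c, b in ineq:
                G_rows.append(-(c @ self.N)[None, :])
                h_rows.append(np.array([c @ v0 - b]))
            self.G = np.vstack(G_rows)
            self.h = np.concatenate(h_rows)
        else:
            self.G = np.zeros((0, 0))
            self.h = np.zeros(0)

    @property
    def dim(self) -> int:
        return self.N.shape[1]

    def interior_point(self) -> np.ndarray:
        """Chebyshev-style strictly interior point (max-min slack LP).

        The minimum-norm start typically sits on a vertex of the polytope,
        where a hit-and-run walk cannot move; the walk starts here instead.
        """
        if self.dim == 0:
            return np.zeros(0)
        norms = np.linalg.norm(self.G, axis=1)
        norms[norms == 0] = 1.0
        c = np.zeros(self.dim + 1)
        c[-1] = -1.0  # maximize t
        A_ub = np.hstack([self.G, norms[:, None]])
        res = optimize.linprog(
            c,
            A_ub=A_ub,
            b_ub=self.h,
            bounds=[(None, None)] * self.dim + [(0, None)],
            method="highs",
        )
        if res.status == 0 and res.x is not None and res.x[-1] > 0:
            return res.x[: self.dim]
        return np.zeros(self.dim)

    def contains(self, alphas: np.ndarray) -> np.ndarray:
        if self.dim == 0:
            return np.ones(len(alphas), dtype=bool)
        return np.all(alphas @ self.G.T <= self.h + 1e-9, axis=1)

    def to_flux(self, alphas: np.ndarray) -> np.ndarray:
        return self.v0 + alphas @ self.N.T


def _hit_and_run(poly: _Polytope, n: int, rng, burn_in: int = 200, thin: int = 5):
    d = poly.dim
    alpha = poly.interior_point()
    slack = poly.h - poly.G @ alpha
    if np.any(slack < -1e-9):
        raise SamplingError("hit-and-run start point infeasible")
    out = np.empty((n, d))
    total = burn_in + n * thin
    k = 0
    for step in range(total):
        u = rng.standard_normal(d)
        u /= np.linalg.norm(u)
        g = poly.G @ u
        slack = poly.h - poly.G @ alpha
        slack = np.maximum(slack, 0.0)
        with np.errstate(divide="ignore"):
            t = slack / g
        pos = g > 1e-14
        neg = g < -1e-14
        t_hi = t[pos].min() if pos.any() else 1e6
        t_lo = -(slack[neg] / -g[neg]).min() if neg.any() else -1e6
        alpha = alpha + u * rng.uniform(t_lo, t_hi)
        if step >= burn_in and (step - burn_in) % thin == thin - 1:
            out[k] = alpha
            k += 1
    return out[:k]


def sample_net_fluxes(
    network: MetabolicNetwork,
    n: int,
    seed: int | np.random.Generator,
    ratio_constraint=None,
    *,
    uptake_reaction: str | None = None,
    uptake_value: float = DEFAULT_UPTAKE,
    flux_bound: float = DEFAULT_FLUX_BOUND,
    extra_constraints=None,
    method: str = "auto",
    v0: np.ndarray | None = None,
    output_min: float | None = None,
) -> np.ndarray:
    """Sample ``n`` steady-state net-flux vectors.

    Gaussian null-space perturbations with rejection are tried first; when
    the acceptance rate drops below 1% the sampler switches to a hit-and-run
    walk over the same polytope (``method`` forces one of "rejection",
    "hitandrun").  Fixed seeds give bit-reproducible cohorts.
    """
    rng = np.random.default_rng(seed)
    if uptake_reaction is None:
        uptake_reaction = find_uptake_reaction(network)
    if output_min is None:
        output_min = 0.01 * abs(uptake_value)
    ineq = list(extra_constraints or [])
    ineq += output_constraints(network, output_min)
    ineq += _ratio_inequalities(
        network, ratio_constraint, den_min=1e-3 * abs(uptake_value)
    )
    if v0 is None:
        v0 = initial_flux(
            network,
            extra_constraints=extra_constraints,
            uptake_reaction=uptake_reaction,
            uptake_value=uptake_value,
            flux_bound=flux_bound,
            ratio_constraint=ratio_constraint,
            output_min=output_min,
        )
    poly = _Polytope(
        network,
        v0,
        uptake_reaction=uptake_reaction,
        flux_bound=flux_bound,
        ineq=ineq,
    )
    if poly.dim == 0:
        return np.tile(v0, (n, 1))

    if method in ("auto", "rejection"):
        # per-direction Gaussian scale matched to the box widths
        lb, ub = flux_bounds(network, flux_bound)
        widths = ub - lb
        with np.errstate(divide="ignore"):
            sig = np.min(
                np.where(np.abs(poly.N) > 1e-12, widths[:, None] / (4 * np.abs(poly.N)), np.inf),
                axis=0,
            )
        sig = np.where(np.isfinite(sig), sig, 1.0)
        accepted = []
        n_drawn = 0
        max_draws = max(200 * n, 20000)
        while sum(len(a) for a in accepted) < n and n_drawn < max_draws:
            batch = max(n, 1000)
            alphas = rng.standard_normal((batch, poly.dim)) * sig
            keep = poly.contains(alphas)
            accepted.append(alphas[keep])
            n_drawn += batch
            got = sum(len(a) for a in accepted)
            if method == "auto" and n_drawn >= 2 * batch and got / n_drawn < 0.01:
                break
        got = sum(len(a) for a in accepted)
        if got >= n:
            alphas = np.vstack(accepted)[:n]
            return poly.to_flux(alphas)
        if method == "rejection":
            raise SamplingError(
                f"rejection sampling produced {got}/{n} samples "
                f"(acceptance rate {got / max(n_drawn, 1):.2%})"
            )
    alphas = _hit_and_run(poly, n, rng)
    return poly.to_flux(alphas)


# ---------------------------------------------------------------------------
# Exchange fluxes


def assign_exchange(
    network: MetabolicNetwork,
    net: np.ndarray,
    exch_bound: float,
    seed: int | np.random.Generator,
    *,
    zero_net_scale: float = DEFAULT_UPTAKE * 1e-3,
) -> np.ndarray:
    """Random exchange fluxes: exch = u * bound * |net|, u ~ Uniform(0, 1).

    Applies to reversible reactions only.  Reversible reactions with
    (numerically) zero net flux still get a small exchange flux
    u * bound * ``zero_net_scale`` so fully equilibrated zero-net reactions
    remain representable.  Works on a single vector or a (n, m) matrix.
    """
    if exch_bound < 0:
        raise SamplingError("exch_bound must be >= 0")
    rng = np.random.default_rng(seed)
    net = np.asarray(net, dtype=float)
    single = net.ndim == 1
    net2 = net[None, :] if single else net
    rev = network.reversible_mask
    u = rng.uniform(0.0, 1.0, size=net2.shape)
    mag = np.abs(net2)
    mag = np.where(mag < 1e-9, zero_net_scale, mag)
    exch = np.where(rev[None, :], u * exch_bound * mag, 0.0)
    return exch[0] if single else exch


# ---------------------------------------------------------------------------
# Ratio evaluation over cohorts and stratified sampling


def infeasible_bin_indices(
    cohort: FluxCohort, ratio_name: str, n_bins: int
) -> list[int] | None:
    """Bin indices recorded as infeasible for ``ratio_name`` when the
    cohort was stratified on it; None when the cohort carries no such
    information for this ratio."""
    meta = cohort.metadata
    strat = meta.get("stratified_on")
    inf = meta.get("infeasible_bins")
    if strat == ratio_name:
        edges = inf or []
    elif isinstance(strat, (list, tuple)) and ratio_name in strat:
        edges = (inf or {}).get(ratio_name, [])
    else:
        return None
    return [int(round(lo * n_bins)) for lo, _ in edges]


def ratio_values(
    ratio_def: RatioDefinition,
    network: MetabolicNetwork,
    net: np.ndarray,
    exch: np.ndarray | None = None,
) -> np.ndarray:
    """Per-sample ratio values; NaN where undefined or outside [0, 1]."""
    num = ratio_def._side_value(ratio_def.numerator, network, net, exch)
    den = ratio_def._side_value(ratio_def.denominator, network, net, exch)
    den = np.asarray(den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.asarray(num, dtype=float) / den
    bad = (den <= 1e-12) | (r < -1e-9) | (r > 1 + 1e-9)
    r = np.where(bad, np.nan, np.clip(r, 0.0, 1.0))
    return r


def stratified_cohort(
    network: MetabolicNetwork,
    ratio_def: RatioDefinition,
    n_bins: int,
    n_per_bin: int,
    exch_bound: float = 1.0,
    seed: int | np.random.Generator = 0,
    *,
    extra_ratio_defs: list[RatioDefinition] | None = None,
    uptake_reaction: str | None = None,
    uptake_value: float = DEFAULT_UPTAKE,
    flux_bound: float = DEFAULT_FLUX_BOUND,
    output_min: float | None = None,
) -> FluxCohort:
    """Sample a cohort with near-uniform coverage of a flux ratio.

    The ratio range [0, 1] is split into ``n_bins`` segments; the flux
    sampling procedure is repeated per segment with the segment end points
    imposed as linear ratio constraints.  Bins that are infeasible for the
    network are skipped with a warning and reported in the metadata.
    """
    if n_bins < 1:
        raise SamplingError("n_bins must be >= 1")
    rng = np.random.default_rng(seed)
    if uptake_reaction is None:
        uptake_reaction = find_uptake_reaction(network)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    nets, infeasible = [], []
    for b in range(n_bins):
        lo, hi = float(edges[b]), float(edges[b + 1])
        try:
            nets.append(
                sample_net_fluxes(
                    network,
                    n_per_bin,
                    rng,
                    ratio_constraint=(ratio_def, lo, hi),
                    uptake_reaction=uptake_reaction,
                    uptake_value=uptake_value,
                    flux_bound=flux_bound,
                    output_min=output_min,
                )
            )
        except InfeasibleError:
            infeasible.append((lo, hi))
            warnings.warn(
                f"ratio '{ratio_def.name}': bin [{lo:.2f}, {hi:.2f}] infeasible; "
                "skipped",
                stacklevel=2,
            )
    if not nets:
        raise SamplingError(
            f"ratio '{ratio_def.name}': no feasible ratio bin in [0, 1]"
        )
    net = np.vstack(nets)
    exch = assign_exchange(
        network, net, exch_bound, rng, zero_net_scale=abs(uptake_value) * 1e-3
    )
    ratios = {ratio_def.name: ratio_values(ratio_def, network, net)}
    for rd in extra_ratio_defs or []:
        ratios[rd.name] = ratio_values(rd, network, net)
    meta = {
        "seed": None if isinstance(seed, np.random.Generator) else int(seed),
        "n_bins": n_bins,
        "n_per_bin": n_per_bin,
        "exch_bound": exch_bound,
        "uptake_reaction": uptake_reaction,
        "uptake_value": uptake_value,
        "flux_bound": flux_bound,
        "stratified_on": ratio_def.name,
        "infeasible_bins": infeasible,
    }
    return FluxCohort(network, net, exch, ratios, meta)


def multi_ratio_cohort(
    network: MetabolicNetwork,
    ratio_defs: list[RatioDefinition],
    n_bins: int,
    n_per_bin: int,
    exch_bound: float = 1.0,
    seed: int = 0,
    **kwargs,
) -> FluxCohort:
    """One shared cohort uniformly covering several ratios.

    Concatenates per-ratio stratified cohorts (every ratio gets its
    ``n_per_bin`` guaranteed samples per feasible bin) and labels every
    sample with every ratio, so several predictors can be trained on the
    same set of flux maps.
    """
    ss = np.random.SeedSequence(seed)
    parts = []
    infeasible: dict[str, list] = {}
    for rd, sub in zip(ratio_defs, ss.spawn(len(ratio_defs))):
        part = stratified_cohort(
            network, rd, n_bins, n_per_bin, exch_bound,
            int(sub.generate_state(1)[0] % 2**31),
            extra_ratio_defs=[r for r in ratio_defs if r.name != rd.name],
            **kwargs,
        )
        infeasible[rd.name] = part.metadata["infeasible_bins"]
        parts.append(part)
    net = np.vstack([p.net for p in parts])
    exch = np.vstack([p.exch for p in parts])
    ratios = {
        rd.name: np.concatenate([p.ratios[rd.name] for p in parts])
        for rd in ratio_defs
    }
    meta = dict(parts[0].metadata)
    meta.update(
        {
            "seed": int(seed),
            "stratified_on": [rd.name for rd in ratio_defs],
            "infeasible_bins": infeasible,
        }
    )
    return FluxCohort(network, net, exch, ratios, meta)
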