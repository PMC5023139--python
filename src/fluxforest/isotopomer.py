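"""Brute-force positional-isotopomer steady state (test oracle).

Solves the full isotopomer balance of every balanced metabolite by explicit
enumeration of all 2^n positional labeling states, then marginalizes to
fragment mass distributions.  All first-order production terms (one
balanced reactant, possibly condensed with substrate pools) are assembled
into one sparse-in-spirit linear system solved directly, which keeps the
oracle exact even at extreme exchange fluxes; genuine condensations of two
balanced pools make the balance bilinear and are relaxed by outer fixed-
point iteration (they are contractive whenever the cycle has throughput).

Only intended for toy networks (the total state count is capped); this is
the independent reference the EMU cascade is checked against.
"""

from __future__ import annotations

import numpy as np

from .emu import _expand_reactions
from .errors import SimulationError
from .labels import SubstrateLabelMixture
from .network import MetabolicNetwork

__all__ = ["brute_force_isotopomers", "isotopomer_distributions"]

_MAX_STATES = 2**16


def _substrate_isotopomers(
    tracer: SubstrateLabelMixture, substrate: str, n_carbons: int
) -> np.ndarray:
    """Distribution over 2^n positional isotopomers (bit i = carbon i labeled)."""
    dist = np.zeros(2**n_carbons)
    for frac, enr in tracer.enrichment_components(substrate, n_carbons):
        comp = np.array([1.0])
        for pos in range(n_carbons):
            p = enr[pos]
            comp = np.concatenate([comp * (1 - p), comp * p])
        dist += frac * comp
    return dist


class _Term:
    """One production event: urxn flux x weight, product instance mapping."""

    def __init__(self, uid, weight, r_mets, mapping, n_out):
        self.uid = uid
        self.weight = weight
        self.r_mets = r_mets          # reactant metabolites, joint-index order
        self.mapping = mapping        # joint state -> product state
        self.n_out = n_out

    def apply(self, dists: list[np.ndarray]) -> np.ndarray:
        joint = np.array([1.0])
        for d in dists:
            joint = np.outer(d, joint).reshape(-1)
        return np.bincount(self.mapping, weights=joint, minlength=self.n_out)


def isotopomer_distributions(
    network: MetabolicNetwork,
    flux_state,
    tracer: SubstrateLabelMixture,
    tol: float = 1e-13,
    max_iter: int = 10000,
) -> dict[str, np.ndarray]:
    """Steady-state isotopomer distribution of every balanced metabolite."""
    tracer.validate()
    carbons = network.metabolites
    balanced = network.balanced_metabolites
    sizes = {m: 2 ** carbons[m] for m in balanced}
    if sum(sizes.values()) > _MAX_STATES:
        raise SimulationError("isotopomer state space too large for brute force")

    urxns = _expand_reactions(network)
    F = np.empty(len(urxns))
    fwd, bwd = flux_state.fwd, flux_state.bwd
    for u in urxns:
        F[u.uid] = fwd[u.rxn_index] if u.forward else bwd[u.rxn_index]

    subs = network.substrates
    sub_dist = {m: _substrate_isotopomers(tracer, m, carbons[m]) for m in subs}

    # term list per balanced metabolite
    terms: dict[str, list[_Term]] = {m: [] for m in balanced}
    for u in urxns:
        r_mets = [occ.metabolite for occ in u.reactants]
        r_sizes = [2 ** carbons[m] for m in r_mets]
        for pi, occ in enumerate(u.products):
            if occ.metabolite not in terms:
                continue
            letters = {
                letter: (ri, pos)
                for ri, rocc in enumerate(u.reactants)
                for pos, letter in enumerate(rocc.atoms)
            }
            strides = np.cumprod([1] + r_sizes)[:-1]
            total = int(np.prod(r_sizes))
            mapping = np.zeros(total, dtype=np.int64)
            joint = np.arange(total)
            for a, letter in enumerate(occ.atoms):
                ri, pos = letters[letter]
                bits = (joint // (strides[ri] * (2**pos))) % 2
                mapping += bits * (2**a)
            terms[occ.metabolite].append(
                _Term(u.uid, u.weight, r_mets, mapping, 2 ** carbons[occ.metabolite])
            )

    # global unknown vector layout
    offset: dict[str, int] = {}
    n_tot = 0
    for m in balanced:
        offset[m] = n_tot
        n_tot += sizes[m]

    D = np.zeros(n_tot)              # diagonal: total influx per pool
    L = np.zeros((n_tot, n_tot))     # first-order production operators
    b_const = np.zeros(n_tot)        # substrate-only terms
    nl_terms: list[tuple[str, _Term, float]] = []

    for m in balanced:
        sl = slice(offset[m], offset[m] + sizes[m])
        total_in = 0.0
        for t in terms[m]:
            v = F[t.uid] * t.weight
            total_in += v
            if v <= 0.0:
                continue
            bal_in = [rm for rm in t.r_mets if rm not in subs]
            if len(bal_in) == 0:
                b_const[sl] += v * t.apply([sub_dist[rm] for rm in t.r_mets])
            elif len(bal_in) == 1:
                rm_b = bal_in[0]
                nb = sizes[rm_b]
                # basis probing builds the term's linear operator exactly
                block = np.empty((sizes[m], nb))
                for j in range(nb):
                    dists = []
                    for rm in t.r_mets:
                        if rm == rm_b:
                            e = np.zeros(nb)
                            e[j] = 1.0
                            dists.append(e)
                        else:
                            dists.append(sub_dist[rm])
                    block[:, j] = t.apply(dists)
                L[sl, offset[rm_b] : offset[rm_b] + nb] += v * block
            else:
                nl_terms.append((m, t, v))
        if total_in <= 0.0:
            raise SimulationError(
                f"metabolite '{m}' has zero influx (disconnected pool)"
            )
        D[sl] = total_in

    A = np.diag(D) - L
    p = np.zeros(n_tot)
    for m in balanced:
        p[offset[m]] = 1.0  # start unlabeled
    for _ in range(max_iter):
        b = b_const.copy()
        for m, t, v in nl_terms:
            dists = [
                sub_dist[rm] if rm in subs
                else p[offset[rm] : offset[rm] + sizes[rm]]
                for rm in t.r_mets
            ]
            b[offset[m] : offset[m] + sizes[m]] += v * t.apply(dists)
        try:
            p_new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            raise SimulationError(
                "singular isotopomer balance (pool without throughput)"
            ) from None
        delta = np.abs(p_new - p).max()
        p = p_new
        if delta < tol:
            break
    else:
        raise SimulationError("isotopomer fixed point did not converge")
    return {m: p[offset[m] : offset[m] + sizes[m]] for m in balanced}


def _marginalize(dist: np.ndarray, atoms: tuple[int, ...]) -> np.ndarray:
    mdv = np.zeros(len(atoms) + 1)
    states = np.arange(len(dist))
    mass = np.zeros(len(dist), dtype=np.int64)
    for a in atoms:
        mass += (states >> a) & 1
    np.add.at(mdv, mass, dist)
    return mdv


def brute_force_isotopomers(
    network: MetabolicNetwork,
    flux_state,
    tracer: SubstrateLabelMixture,
    targets: list[tuple[str, tuple[int, ...]]],
) -> dict[tuple[str, tuple[int, ...]], np.ndarray]:
    """Fragment MDVs from full isotopomer enumeration (oracle path)."""
    dist = None
    out = {}
    for m, atoms in targets:
        atoms = tuple(sorted(int(a) for a in atoms))
        if m in network.substrates:
            out[(m, atoms)] = tracer.emu_mdv(m, atoms)
            continue
        if dist is None:
            dist = isotopomer_distributions(network, flux_state, tracer)
        out[(m, atoms)] = _marginalize(dist[m], atoms)
    return out
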