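"""Steady-state 13C label propagation via elementary metabolite units (EMU).

An EMU is a specific subset of a metabolite's carbon atoms.  The EMU
decomposition reduces the (exponentially large) isotopomer balance to a
cascade of linear systems ordered by EMU size: at each size level the mass
distribution vectors (MDVs) of all required EMUs solve

    A(v) X = -B(v) Y

where A collects flux-weighted mixing between same-size EMUs of balanced
metabolites, and Y collects known inputs — substrate-fragment MDVs from the
tracer mixture and convolutions (Cauchy products) of smaller EMUs already
solved.  The decomposition depends only on network structure and is cached,
so only matrix values change between flux samples; simulation is vectorized
over whole cohorts of flux maps.

Reversible reactions are expanded into forward and backward unidirectional
reactions weighted by the forward/backward fluxes.  Rotationally symmetric
metabolites are handled by splitting every production of such a metabolite
into the stated and the carbon-reversed atom map, each with weight 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SimulationError
from .labels import SubstrateLabelMixture
from .network import MetabolicNetwork, Occurrence

__all__ = ["MDV", "EMUSystem", "emu_decompose", "convolve", "simulate_mdvs",
           "expanded_fluxes"]


def convolve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cauchy product of two mass distribution vectors."""
    return np.convolve(np.asarray(a, float), np.asarray(b, float))


def _conv_batch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Convolve along the last axis; ``a`` is (n, la), ``b`` (n, lb) or (lb,)."""
    n, la = a.shape
    lb = b.shape[-1]
    out = np.zeros((n, la + lb - 1))
    if b.ndim == 1:
        for k in range(lb):
            out[:, k : k + la] += a * b[k]
    else:
        for k in range(lb):
            out[:, k : k + la] += a * b[:, k][:, None]
    return out


@dataclass
class MDV:
    """Mass distribution vector: fractions of M+0 ... M+n molecules."""

    fractions: np.ndarray

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        if np.any(self.fractions < -1e-9):
            raise SimulationError("MDV has negative fraction beyond tolerance")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise SimulationError("MDV does not sum to 1")

    def __len__(self):
        return len(self.fractions)


# ---------------------------------------------------------------------------
# Unidirectional expansion


@dataclass(frozen=True)
class _UniRxn:
    uid: int
    rxn_index: int
    forward: bool
    weight: float
    reactants: tuple[Occurrence, ...]
    products: tuple[Occurrence, ...]


def _expand_reactions(network: MetabolicNetwork) -> list[_UniRxn]:
    """Forward/backward expansion with symmetric-metabolite map splitting."""
    sym = network.symmetric_metabolites
    out: list[_UniRxn] = []
    uid = 0
    for j, r in enumerate(network.reactions):
        directions = [(True, r.reactants, r.products)]
        if r.reversible:
            directions.append((False, r.products, r.reactants))
        for fwd, reac, prod in directions:
            variants = [(1.0, list(prod))]
            for pi, occ in enumerate(prod):
                if occ.metabolite in sym and len(occ.atoms) > 1:
                    new = []
                    for w, plist in variants:
                        rev = Occurrence(occ.metabolite, occ.atoms[::-1])
                        new.append((w * 0.5, plist))
                        alt = list(plist)
                        alt[pi] = rev
                        new.append((w * 0.5, alt))
                    variants = new
            for w, plist in variants:
                out.append(
                    _UniRxn(uid, j, fwd, w, tuple(reac), tuple(plist))
                )
                uid += 1
    return out


def expanded_fluxes(urxns: list[_UniRxn], fwd: np.ndarray, bwd: np.ndarray):
    """Flux matrix over expanded reactions from forward/backward fluxes.

    ``fwd``/``bwd`` are (n_samples, n_reactions) or 1-D vectors.
    """
    fwd = np.atleast_2d(np.asarray(fwd, float))
    bwd = np.atleast_2d(np.asarray(bwd, float))
    F = np.empty((fwd.shape[0], len(urxns)))
    for u in urxns:
        F[:, u.uid] = fwd[:, u.rxn_index] if u.forward else bwd[:, u.rxn_index]
    return F


# ---------------------------------------------------------------------------
# Decomposition

EMUKey = tuple[str, tuple[int, ...]]  # (metabolite, sorted 0-based atoms)


@dataclass
class _Term:
    uid: int
    weight: float
    sources: list[tuple[EMUKey, bool]]  # (key, is_substrate)


class EMUSystem:
    """Cached EMU decomposition of a network for a fixed set of targets."""

    def __init__(self, network: MetabolicNetwork, targets: list[EMUKey]):
        self.network = network
        self.targets = [
            (m, tuple(sorted(int(a) for a in atoms))) for m, atoms in targets
        ]
        carbons = network.metabolites
        for m, atoms in self.targets:
            if m not in carbons:
                raise SimulationError(f"target fragment on unknown metabolite '{m}'")
            if not atoms or atoms[-1] >= carbons[m]:
                raise SimulationError(
                    f"target fragment atoms {atoms} outside '{m}' "
                    f"({carbons[m]} carbons)"
                )
        self.urxns = _expand_reactions(network)
        self._producers: dict[str, list[tuple[_UniRxn, int]]] = {}
        for u in self.urxns:
            for pi, occ in enumerate(u.products):
                self._producers.setdefault(occ.metabolite, []).append((u, pi))
        self._decompose()
        self._build_index()
        self._build_liveness()

    # -- structure ----------------------------------------------------------
    def _terms_for(self, key: EMUKey) -> list[_Term]:
        met, atoms = key
        subs = self.network.substrates
        terms = []
        for u, pi in self._producers.get(met, []):
            occ = u.products[pi]
            # origin of each kept atom
            origin: dict[int, list[int]] = {}
            letters = {
                letter: (ri, pos)
                for ri, rocc in enumerate(u.reactants)
                for pos, letter in enumerate(rocc.atoms)
            }
            for a in atoms:
                ri, pos = letters[occ.atoms[a]]
                origin.setdefault(ri, []).append(pos)
            sources = []
            for ri in sorted(origin):
                src_met = u.reactants[ri].metabolite
                src_key = (src_met, tuple(sorted(origin[ri])))
                sources.append((src_key, src_met in subs))
            terms.append(_Term(u.uid, u.weight, sources))
        return terms

    def _decompose(self) -> None:
        subs = self.network.substrates
        self.terms: dict[EMUKey, list[_Term]] = {}
        stack = [
            (m, atoms) for m, atoms in self.targets if m not in subs
        ]
        seen = set(stack)
        while stack:
            key = stack.pop()
            terms = self._terms_for(key)
            if not terms:
                raise SimulationError(
                    f"EMU {key[0]}{list(a + 1 for a in key[1])} is unreachable: "
                    "no producing reaction"
                )
            self.terms[key] = terms
            for t in terms:
                for src, is_sub in t.sources:
                    if not is_sub and src not in seen:
                        seen.add(src)
                        stack.append(src)

    def _build_index(self) -> None:
        sizes = sorted({len(k[1]) for k in self.terms})
        self.levels = []
        index: dict[EMUKey, int] = {}
        for s in sizes:
            unknowns = sorted(k for k in self.terms if len(k[1]) == s)
            for i, k in enumerate(unknowns):
                index[k] = i
            internal = []  # (row, col, uid, w)
            inputs = []    # (row, uid, w, sources)
            diag = []      # (row, uid, w)
            for k in unknowns:
                row = index[k]
                for t in self.terms[k]:
                    diag.append((row, t.uid, t.weight))
                    if len(t.sources) == 1 and not t.sources[0][1]:
                        internal.append((row, index[t.sources[0][0]], t.uid, t.weight))
                    else:
                        inputs.append((row, t.uid, t.weight, t.sources))
            self.levels.append(
                {
                    "size": s,
                    "unknowns": unknowns,
                    "internal": internal,
                    "inputs": inputs,
                    "diag": diag,
                }
            )
        self.index = index

    def _build_liveness(self) -> None:
        """Metabolite-level production terms used to find dead pools.

        A balanced pool is live when it transitively receives material from
        a substrate through reactions with non-negligible flux.  A term
        feeds its product as soon as one of its reactant pools is fed:
        because the sampled fluxes satisfy the steady-state balance, a
        reaction can only carry flux if every one of its reactant pools
        has matching throughput, so one fed reactant certifies them all.
        Pools that fail this are closed sub-loops (e.g. circulating purely
        on exchange fluxes) or shut-off branches: their isotopic state is
        ill-defined but irrelevant, since every flux coupling them to live
        pools is below the threshold.
        """
        mets = sorted({k[0] for k in self.terms})
        self._live_mets = {m: i for i, m in enumerate(mets)}
        subs = self.network.substrates
        prod: dict[tuple[str, int, tuple[int, ...], bool], None] = {}
        for u in self.urxns:
            for occ in u.products:
                if occ.metabolite not in self._live_mets:
                    continue
                bal = tuple(
                    sorted(
                        {
                            self._live_mets[r.metabolite]
                            for r in u.reactants
                            if r.metabolite in self._live_mets
                        }
                    )
                )
                from_sub = any(r.metabolite in subs for r in u.reactants)
                prod[(occ.metabolite, u.uid, bal, from_sub)] = None
        self._live_terms = [
            (self._live_mets[m], uid, bal, from_sub)
            for (m, uid, bal, from_sub) in prod
        ]

    def _live_mask(self, F: np.ndarray, delta: float = 1e-6) -> np.ndarray:
        """(n_samples, n_mets) bool: which balanced pools carry material."""
        n = F.shape[0]
        live = np.zeros((n, len(self._live_mets)), dtype=bool)
        for _ in range(len(self._live_mets) + 1):
            changed = False
            for mi, uid, bal, from_sub in self._live_terms:
                ok = F[:, uid] > delta
                if not from_sub:
                    any_fed = np.zeros(n, dtype=bool)
                    for bi in bal:
                        any_fed |= live[:, bi]
                    ok &= any_fed
                new = live[:, mi] | ok
                if not np.array_equal(new, live[:, mi]):
                    live[:, mi] = new
                    changed = True
            if not changed:
                break
        return live

    @property
    def n_emus(self) -> int:
        return len(self.terms)

    @property
    def max_size(self) -> int:
        return max(lv["size"] for lv in self.levels)

    # -- simulation ---------------------------------------------------------
    def _substrate_mdv(self, tracer: SubstrateLabelMixture, key: EMUKey):
        return tracer.emu_mdv(key[0], key[1])

    def simulate(
        self,
        fwd: np.ndarray,
        bwd: np.ndarray,
        tracer: SubstrateLabelMixture,
        chunk: int = 1024,
    ) -> dict[EMUKey, np.ndarray]:
        """MDVs of all targets for a batch of flux maps.

        ``fwd``/``bwd`` are (n_samples, n_reactions); returns target key ->
        (n_samples, size+1) arrays.
        """
        tracer.validate()
        F = expanded_fluxes(self.urxns, fwd, bwd)
        n = F.shape[0]
        out = {k: np.empty((n, len(k[1]) + 1)) for k in self.targets}
        for lo in range(0, n, chunk):
            hi = min(lo + chunk, n)
            solved = self._simulate_chunk(F[lo:hi], tracer)
            for k in self.targets:
                if k[0] in self.network.substrates:
                    out[k][lo:hi] = self._substrate_mdv(tracer, k)[None, :]
                else:
                    out[k][lo:hi] = solved[k]
        for k in self.targets:
            sums = out[k].sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-6):
                i = int(np.argmax(np.abs(sums - 1.0)))
                met, atoms = k
                raise SimulationError(
                    f"measured EMU {met}{[a + 1 for a in atoms]} has zero "
                    f"throughput in sample {i}; its MDV is undefined"
                )
        return out

    def _simulate_chunk(self, F, tracer):
        n = F.shape[0]
        live = self._live_mask(F)
        for met, atoms in self.targets:
            if met in self._live_mets and not live[:, self._live_mets[met]].all():
                i = int(np.argmin(live[:, self._live_mets[met]]))
                raise SimulationError(
                    f"measured metabolite '{met}' has zero throughput in "
                    f"sample {i}; its MDV is undefined"
                )
        solved: dict[EMUKey, np.ndarray] = {}
        sub_cache: dict[EMUKey, np.ndarray] = {}

        def source_mdv(src, is_sub):
            if is_sub:
                if src not in sub_cache:
                    sub_cache[src] = self._substrate_mdv(tracer, src)
                return sub_cache[src]
            return solved[src]

        for lv in self.levels:
            m = len(lv["unknowns"])
            L = lv["size"] + 1
            A = np.zeros((n, m, m))
            rhs = np.zeros((n, m, L))
            for row, uid, w in lv["diag"]:
                A[:, row, row] -= F[:, uid] * w
            for row, col, uid, w in lv["internal"]:
                A[:, row, col] += F[:, uid] * w
            for row, uid, w, sources in lv["inputs"]:
                y = None
                for src, is_sub in sources:
                    s_mdv = source_mdv(src, is_sub)
                    if y is None:
                        y = np.broadcast_to(s_mdv, (n, len(s_mdv))) if s_mdv.ndim == 1 else s_mdv
                        y = np.array(y)
                    else:
                        y = _conv_batch(y, s_mdv)
                rhs[:, row, :] -= (F[:, uid] * w)[:, None] * y
            # dead pools (no material path from a substrate): pin their MDV
            # to unlabeled so the solve stays regular; every flux coupling
            # them to live pools is below the liveness threshold, and dead
            # *measured* pools are caught by the target check afterwards.
            met_cols = np.array(
                [self._live_mets[k[0]] for k in lv["unknowns"]], dtype=int
            )
            diag = A[:, np.arange(m), np.arange(m)]
            dead = ~live[:, met_cols] | (np.abs(diag) < 1e-9)
            if dead.any():
                si, ui = np.nonzero(dead)
                A[si, ui, :] = 0.0
                A[si, ui, ui] = 1.0
                rhs[si, ui, :] = 0.0
                rhs[si, ui, 0] = 1.0
            try:
                X = np.linalg.solve(A, rhs)
            except np.linalg.LinAlgError as e:
                raise SimulationError(
                    f"singular EMU balance at size {lv['size']}: {e}"
                ) from None
            # tolerance scaled for rare poorly conditioned live-but-barely
            # loops; genuinely broken balances blow far past this
            if X.min() < -1e-6:
                raise SimulationError(
                    f"negative EMU fraction {X.min():.3e} at size {lv['size']}"
                )
            X = np.clip(X, 0.0, None)
            for k in lv["unknowns"]:
                solved[k] = X[:, self.index[k], :]
        return solved


def emu_decompose(network: MetabolicNetwork, targets: list[EMUKey]) -> EMUSystem:
    """Build (and cache in the returned object) the EMU decomposition."""
    return EMUSystem(network, targets)


def simulate_mdvs(
    emu_system: EMUSystem,
    flux_state,
    tracer: SubstrateLabelMixture,
) -> dict[EMUKey, MDV]:
    """Single flux-map convenience wrapper returning :class:`MDV` objects."""
    res = emu_system.simulate(
        flux_state.fwd[None, :], flux_state.bwd[None, :], tracer
    )
    return {k: MDV(v[0]) for k, v in res.items()}
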