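"""Measurable 13C features: fragment specs, extraction, and noise.

A measurement spec lists the metabolite fragments (ordered carbon subsets)
accessible on a platform (GC-MS amino acids, LC-MS intact metabolites,
LC-MS/MS fragments, MRM traces).  Simulated fragment MDVs are flattened
into a feature vector with a deterministic manifest
(``<fragment_id>.M+<k>``); measurement noise is additive uniform on
[-eps, +eps] per entry, followed by clipping at zero and renormalization of
each fragment block to sum 1 — mirroring how measured mass-isotopomer
fractions are normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MeasurementError
from .network import MetabolicNetwork

__all__ = ["Fragment", "MeasurementSpec", "extract_features", "add_noise",
           "read_mdv_table"]

PLATFORMS = ("gcms", "lcms", "lcmsms", "mrm")


@dataclass(frozen=True)
class Fragment:
    """A measurable carbon subset of a metabolite.

    ``positions`` are 1-based biochemical carbon numbers, strictly
    increasing (files and constructors use 1-based; internal simulation
    code converts to 0-based).
    """

    id: str
    metabolite: str
    positions: tuple[int, ...]

    def __post_init__(self):
        if not self.positions:
            raise MeasurementError(f"fragment '{self.id}': empty carbon subset")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise MeasurementError(
                f"fragment '{self.id}': positions must be strictly increasing"
            )
        if self.positions[0] < 1:
            raise MeasurementError(f"fragment '{self.id}': positions are 1-based")

    @property
    def atoms(self) -> tuple[int, ...]:
        """0-based atom indices for the simulator."""
        return tuple(p - 1 for p in self.positions)

    @property
    def n_carbons(self) -> int:
        return len(self.positions)


@dataclass
class MeasurementSpec:
    fragments: list[Fragment]
    platform: str = "gcms"
    name: str = ""

    def __post_init__(self):
        if self.platform not in PLATFORMS:
            raise MeasurementError(
                f"unknown platform '{self.platform}'; expected one of {PLATFORMS}"
            )
        ids = [f.id for f in self.fragments]
        if len(set(ids)) != len(ids):
            raise MeasurementError("duplicate fragment ids in measurement spec")

    def validate(self, network: MetabolicNetwork) -> None:
        carbons = network.metabolites
        for f in self.fragments:
            if f.metabolite not in carbons:
                raise MeasurementError(
                    f"fragment '{f.id}': unknown metabolite '{f.metabolite}'"
                )
            if f.positions[-1] > carbons[f.metabolite]:
                raise MeasurementError(
                    f"fragment '{f.id}': position {f.positions[-1]} exceeds "
                    f"{f.metabolite}'s {carbons[f.metabolite]} carbons"
                )

    @property
    def targets(self) -> list[tuple[str, tuple[int, ...]]]:
        """EMU targets (0-based) needed to simulate this spec."""
        return [(f.metabolite, f.atoms) for f in self.fragments]

    @property
    def manifest(self) -> list[str]:
        """Deterministic feature names: fragment blocks of M+0..M+n entries."""
        return [
            f"{f.id}.M+{k}" for f in self.fragments for k in range(f.n_carbons + 1)
        ]

    @property
    def blocks(self) -> list[tuple[int, int]]:
        """(start, stop) feature-column slices, one per fragment."""
        out = []
        start = 0
        for f in self.fragments:
            stop = start + f.n_carbons + 1
            out.append((start, stop))
            start = stop
        return out

    @property
    def n_features(self) -> int:
        return sum(f.n_carbons + 1 for f in self.fragments)

    @classmethod
    def from_dict(cls, d: dict) -> "MeasurementSpec":
        frags = [
            Fragment(f["id"], f["metabolite"], tuple(int(p) for p in f["positions"]))
            for f in d["fragments"]
        ]
        return cls(frags, d.get("platform", "gcms"), d.get("name", ""))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "platform": self.platform,
            "fragments": [
                {"id": f.id, "metabolite": f.metabolite, "positions": list(f.positions)}
                for f in self.fragments
            ],
        }


def extract_features(
    mdvs: dict[tuple[str, tuple[int, ...]], np.ndarray], spec: MeasurementSpec
) -> np.ndarray:
    """Flatten simulated fragment MDVs into the spec's feature matrix.

    ``mdvs`` maps (metabolite, 0-based atoms) to (n_samples, n+1) arrays
    (or 1-D vectors).  Values pass through unchanged; ordering follows the
    manifest.  Missing fragments raise naming the fragment.
    """
    if not spec.fragments:
        raise MeasurementError("measurement spec has no fragments")
    cols = []
    for f in spec.fragments:
        key = (f.metabolite, f.atoms)
        if key not in mdvs:
            raise MeasurementError(
                f"fragment '{f.id}' ({f.metabolite} C{list(f.positions)}) "
                "was not simulated"
            )
        arr = np.asarray(mdvs[key], dtype=float)
        cols.append(arr[None, :] if arr.ndim == 1 else arr)
    return np.hstack(cols)


def add_noise(
    features: np.ndarray,
    noise_level: float,
    seed: int | np.random.Generator,
    spec: MeasurementSpec,
) -> np.ndarray:
    """Additive uniform noise on [-eps, +eps], clip at 0, renormalize blocks."""
    if noise_level < 0:
        raise MeasurementError("noise_level must be >= 0")
    if noise_level == 0:
        return np.asarray(features, dtype=float).copy()
    X = np.atleast_2d(np.asarray(features, dtype=float)).copy()
    rng = np.random.default_rng(seed)
    X = X + rng.uniform(-noise_level, noise_level, size=X.shape)
    X = np.clip(X, 0.0, None)
    for start, stop in spec.blocks:
        s = X[:, start:stop].sum(axis=1, keepdims=True)
        if np.any(s <= 0):
            raise MeasurementError("fragment block summed to zero after noising")
        X[:, start:stop] /= s
    return X if np.asarray(features).ndim > 1 else X[0]


def read_mdv_table(path_or_buf, spec: MeasurementSpec) -> np.ndarray:
    """Read experimental MDVs (delimited text) aligned to the spec manifest.

    Expected columns: ``fragment``, ``mass`` (the k of M+k), ``fraction``,
    and optionally ``sample``; one row per fragment mass isotopomer.
    Returns an (n_samples, n_features) matrix in manifest order.
    """
    import pandas as pd

    df = pd.read_csv(path_or_buf, sep=None, engine="python")
    need = {"fragment", "mass", "fraction"}
    if not need.issubset(df.columns):
        raise MeasurementError(
            f"MDV table must have columns {sorted(need)}; got {list(df.columns)}"
        )
    if "sample" not in df.columns:
        df = df.assign(sample="sample0")
    manifest = spec.manifest
    col_of = {name: i for i, name in enumerate(manifest)}
    samples = list(dict.fromkeys(df["sample"]))
    X = np.full((len(samples), len(manifest)), np.nan)
    row_of = {s: i for i, s in enumerate(samples)}
    for _, rec in df.iterrows():
        name = f"{rec['fragment']}.M+{int(rec['mass'])}"
        if name not in col_of:
            raise MeasurementError(
                f"MDV table row '{rec['fragment']}' M+{int(rec['mass'])} does not "
                "match the measurement spec manifest"
            )
        X[row_of[rec["sample"]], col_of[name]] = float(rec["fraction"])
    if np.isnan(X).any():
        missing = [manifest[j] for j in np.argwhere(np.isnan(X))[:, 1][:5]]
        raise MeasurementError(f"MDV table is missing entries, e.g. {missing}")
    return X
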