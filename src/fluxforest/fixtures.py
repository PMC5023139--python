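"""Bundled networks, tracers, measurement specs, and ratio definitions.

Everything here is loadable by name and self-contained: deterministic toy
networks with closed-form expectations (for oracle tests), glucose tracer
builders, per-platform measurement specs, and the two reconstructed
central-carbon reference models (*E. coli*, *B. subtilis*) with their
canonical flux-ratio definitions.

The reference networks are reconstructions from standard central-carbon
biochemistry; the GC-MS fragment set is the standard proteinogenic
amino-acid-to-precursor mapping (fragments are expressed directly on the
precursor metabolites, assuming measured MDVs were corrected to the carbon
backbone).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import FluxForestError
from .labels import SubstrateLabelMixture, parse_label
from .measurements import Fragment, MeasurementSpec
from .network import MetabolicNetwork, parse_network
from .ratios import RatioDefinition, RatioTerm

__all__ = [
    "Fixture",
    "toy_chain",
    "toy_diamond",
    "toy_condensation",
    "make_two_source_fixture",
    "make_cycle_fixture",
    "make_symmetric_fixture",
    "glucose_tracer",
    "DESIGN_TRACERS",
    "gcms_spec",
    "lcms_spec",
    "lcmsms_spec",
    "mrm_spec",
    "platform_spec",
    "load_reference_model",
]


@dataclass
class Fixture:
    """A network bundled with tracer, measurement spec, and ratio defs."""

    network: MetabolicNetwork
    tracer: SubstrateLabelMixture
    spec: MeasurementSpec
    ratio_defs: list[RatioDefinition] = field(default_factory=list)
    expectations: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Toy networks

_CHAIN = """
@substrate s
upt: s (ab) -> b (ab)
r2: b (ab) -> c (ab)
out_c: c (ab) ->
"""

_DIAMOND = """
@substrate s
upt: s (ab) -> a (ab)
u: a (ab) -> b (ab)
v: a (ab) -> b (ab)
out_b: b (ab) ->
"""

_CONDENSATION = """
@substrate s
upt: s (abcd) -> m (abcd)
split: m (abcd) -> x (ab) + y (cd)
flip: x (ab) -> w (ba)
cond: w (ab) + y (cd) -> c (abcd)
out_c: c (abcd) ->
"""

_TWO_SOURCE = """
@substrate sa sb
ua: sa (ab) -> p (ab)
ub: sb (ab) -> p (ab)
out_p: p (ab) ->
"""

_CYCLE = """
@substrate s
upt: s (ab) -> ac (ab)
anap: s (ab) -> oax (ab)
cs: ac (ab) + oax (cd) -> cit (abcd)
cleave: cit (abcd) -> oax (bc) + co (a) + co (d)
out_ac: ac (ab) ->
out_oax: oax (ab) ->
out_co: co (a) ->
@symmetric oax
"""

_SYMMETRIC = """
@substrate s
upt: s (abcd) -> a (abcd)
iso: a (abcd) <-> f (dcba)
out_a: a (abcd) ->
out_f: f (abcd) ->
@symmetric f
"""


def toy_chain() -> MetabolicNetwork:
    """Linear chain with identity atom maps (MDVs pass through unchanged)."""
    return parse_network(_CHAIN)


def toy_diamond() -> MetabolicNetwork:
    """Two parallel routes a -> b; one degree of freedom (the branch split)."""
    return parse_network(_DIAMOND)


def toy_condensation() -> MetabolicNetwork:
    """Cleavage + recombination with a carbon permutation (tests convolution)."""
    return parse_network(_CONDENSATION)


def _uniform_label_tracer(substrate: str, positions, n_carbons: int,
                          natural_abundance: float = 0.0):
    return parse_label(
        {
            "substrate": substrate,
            "natural_abundance": natural_abundance,
            "components": [{"fraction": 1.0, "positions": list(positions)}],
        },
        n_carbons,
    )


def make_two_source_fixture(f: float | None = None) -> Fixture:
    """Mixing-node fixture: product MDV = f*MDV(A) + (1-f)*MDV(B) exactly.

    Two substrates with distinct labels feed one product pool; the ratio
    label is the fractional contribution of substrate A.  ``f`` (optional)
    records the nominal mixing fraction in the expectations.
    """
    network = parse_network(_TWO_SOURCE)
    tracer = parse_label(
        {
            "natural_abundance": 0.0,
            "substrates": [
                {"substrate": "sa",
                 "components": [{"fraction": 1.0, "positions": [1]}]},
                {"substrate": "sb",
                 "components": [{"fraction": 1.0, "positions": []}]},
            ],
        },
        {"sa": 2, "sb": 2},
    )
    spec = MeasurementSpec(
        [
            Fragment("p_12", "p", (1, 2)),
            Fragment("p_1", "p", (1,)),
            Fragment("p_2", "p", (2,)),
        ],
        platform="lcms",
        name="two_source",
    )
    ratio = RatioDefinition(
        "frac_a", [RatioTerm("ua")], [RatioTerm("ua"), RatioTerm("ub")]
    )
    exp = {"mdv_a": np.array([0.0, 1.0, 0.0]), "mdv_b": np.array([1.0, 0.0, 0.0])}
    if f is not None:
        if not 0.0 <= f <= 1.0:
            raise FluxForestError("mixing fraction must lie in [0, 1]")
        exp["f"] = float(f)
        exp["mdv_p"] = f * exp["mdv_a"] + (1 - f) * exp["mdv_b"]
    return Fixture(network, tracer, spec, [ratio], exp)


def make_cycle_fixture() -> Fixture:
    """Condensation cycle with a symmetric intermediate (TCA-like recycling)."""
    network = parse_network(_CYCLE)
    tracer = _uniform_label_tracer("s", [1], 2)
    spec = MeasurementSpec(
        [
            Fragment("oax_12", "oax", (1, 2)),
            Fragment("cit_1234", "cit", (1, 2, 3, 4)),
            Fragment("co_1", "co", (1,)),
        ],
        platform="lcms",
        name="cycle",
    )
    return Fixture(network, tracer, spec, [], {})


def make_symmetric_fixture() -> Fixture:
    """Reversible C4 <-> carbon-reversed C4 with a symmetric partner pool."""
    network = parse_network(_SYMMETRIC)
    tracer = _uniform_label_tracer("s", [1, 2], 4)
    spec = MeasurementSpec(
        [
            Fragment("a_1234", "a", (1, 2, 3, 4)),
            Fragment("f_1234", "f", (1, 2, 3, 4)),
            Fragment("a_12", "a", (1, 2)),
        ],
        platform="lcms",
        name="symmetric",
    )
    return Fixture(network, tracer, spec, [], {})


# ---------------------------------------------------------------------------
# Glucose tracers

GLUCOSE = "glc.ext"


def glucose_tracer(kind: str, natural_abundance: float = 0.0107,
                   purity: float = 1.0) -> SubstrateLabelMixture:
    """Named glucose labeling strategies.

    ``kind``: positional strings like ``"1"``, ``"1,2"``, ``"4,5,6"``
    (100% of glucose labeled at those carbons), or ``"U<percent>"`` for a
    mixture of uniformly labeled and naturally labeled glucose, e.g.
    ``"U20"`` = 20% [U-13C] + 80% natural.  ``"1-80/U-20"`` style mixes of a
    positional and the uniform tracer are written ``"80x1+20xU"``.
    """
    comps = []
    if kind.upper().startswith("U"):
        frac = float(kind[1:]) / 100.0 if len(kind) > 1 else 1.0
        comps.append({"fraction": frac, "uniform": True, "purity": purity})
        if frac < 1.0:
            comps.append({"fraction": 1.0 - frac, "positions": []})
    elif "+" in kind:
        for part in kind.split("+"):
            pct, label = part.split("x")
            frac = float(pct) / 100.0
            if label.upper() == "U":
                comps.append({"fraction": frac, "uniform": True, "purity": purity})
            else:
                comps.append(
                    {"fraction": frac,
                     "positions": [int(p) for p in label.split(",")],
                     "purity": purity}
                )
    else:
        comps.append(
            {"fraction": 1.0,
             "positions": [int(p) for p in kind.split(",")],
             "purity": purity}
        )
    mix = parse_label(
        {"substrate": GLUCOSE, "natural_abundance": natural_abundance,
         "components": comps, "name": f"glucose[{kind}]"},
        6,
    )
    return mix


#: the eight glucose labeling strategies scanned in the design example
DESIGN_TRACERS = ("1", "2", "6", "1,2", "5,6", "4,5,6", "U50", "U20")


# ---------------------------------------------------------------------------
# Measurement specs

# GC-MS of proteinogenic amino acids, expressed on their precursor
# metabolites (21 fragments): full backbones plus the usual C1-loss and
# C1-C2 fragments of the silylated derivatives.
_GCMS_FRAGMENTS = [
    ("pyr_123", "pyr", (1, 2, 3)),     # Ala
    ("pyr_23", "pyr", (2, 3)),
    ("pyr_12", "pyr", (1, 2)),
    ("oaa_1234", "oaa", (1, 2, 3, 4)),  # Asp/Thr
    ("oaa_234", "oaa", (2, 3, 4)),
    ("oaa_12", "oaa", (1, 2)),
    ("oaa_34", "oaa", (3, 4)),
    ("akg_12345", "akg", (1, 2, 3, 4, 5)),  # Glu/Pro
    ("akg_2345", "akg", (2, 3, 4, 5)),
    ("akg_12", "akg", (1, 2)),
    ("akg_345", "akg", (3, 4, 5)),
    ("pga_123", "pga", (1, 2, 3)),     # Ser
    ("pga_23", "pga", (2, 3)),
    ("pga_12", "pga", (1, 2)),         # Gly
    ("pep_123", "pep", (1, 2, 3)),     # Phe/Tyr backbone
    ("pep_23", "pep", (2, 3)),
    ("r5p_12345", "r5p", (1, 2, 3, 4, 5)),  # His
    ("r5p_2345", "r5p", (2, 3, 4, 5)),
    ("e4p_1234", "e4p", (1, 2, 3, 4)),  # aromatic precursor
    ("accoa_12", "accoa", (1, 2)),     # Leu/Ile acetyl unit
    ("g6p_123456", "g6p", (1, 2, 3, 4, 5, 6)),  # glycogen glucose
]

# LC-MS of intact intracellular metabolites (full carbon backbones)
_LCMS_METABOLITES = [
    "g6p", "f6p", "fbp", "pg6", "dhap", "pga", "pep", "pyr",
    "r5p", "s7p", "e4p", "cit", "akg", "suc", "fum", "mal", "oaa", "accoa",
]

# LC-MS/MS: intact metabolites plus characteristic product-ion fragments
_LCMSMS_EXTRA = [
    ("pep_f12", "pep", (1, 2)),
    ("pga_f23", "pga", (2, 3)),
    ("mal_f12", "mal", (1, 2)),
    ("mal_f34", "mal", (3, 4)),
    ("cit_f123", "cit", (1, 2, 3)),
    ("akg_f12", "akg", (1, 2)),
    ("akg_f45", "akg", (4, 5)),
    ("oaa_f12", "oaa", (1, 2)),
    ("fbp_f123", "fbp", (1, 2, 3)),
    ("g6p_f123", "g6p", (1, 2, 3)),
]


def _filtered(frags, network):
    carbons = network.metabolites
    return [
        Fragment(fid, met, pos)
        for fid, met, pos in frags
        if met in carbons and pos[-1] <= carbons[met]
    ]


def gcms_spec(network: MetabolicNetwork) -> MeasurementSpec:
    """Amino-acid GC-MS fragment set mapped onto precursor metabolites."""
    return MeasurementSpec(_filtered(_GCMS_FRAGMENTS, network), "gcms", "gcms")


def lcms_spec(network: MetabolicNetwork) -> MeasurementSpec:
    frags = [
        (f"{m}_full", m, tuple(range(1, network.metabolites[m] + 1)))
        for m in _LCMS_METABOLITES
        if m in network.metabolites
    ]
    return MeasurementSpec(_filtered(frags, network), "lcms", "lcms")


def lcmsms_spec(network: MetabolicNetwork) -> MeasurementSpec:
    frags = [
        (f"{m}_full", m, tuple(range(1, network.metabolites[m] + 1)))
        for m in _LCMS_METABOLITES
        if m in network.metabolites
    ] + _LCMSMS_EXTRA
    return MeasurementSpec(_filtered(frags, network), "lcmsms", "lcmsms")


def mrm_spec(network: MetabolicNetwork) -> MeasurementSpec:
    """All contiguous carbon windows of the LC-MS metabolites (MRM traces)."""
    carbons = network.metabolites
    frags = []
    for m in _LCMS_METABOLITES:
        if m not in carbons:
            continue
        n = carbons[m]
        for start in range(1, n + 1):
            for stop in range(start, n + 1):
                if (start, stop) == (1, n) or stop > start:
                    frags.append(
                        (f"{m}_mrm{start}{stop}", m, tuple(range(start, stop + 1)))
                    )
    return MeasurementSpec(_filtered(frags, network), "mrm", "mrm")


_PLATFORM_BUILDERS = {
    "gcms": gcms_spec,
    "lcms": lcms_spec,
    "lcmsms": lcmsms_spec,
    "mrm": mrm_spec,
}


def platform_spec(platform: str, network: MetabolicNetwork) -> MeasurementSpec:
    if platform not in _PLATFORM_BUILDERS:
        raise FluxForestError(f"unknown measurement platform '{platform}'")
    return _PLATFORM_BUILDERS[platform](network)


# ---------------------------------------------------------------------------
# Reference models

def _rd(name, num, den):
    return RatioDefinition(
        name, [RatioTerm(r) for r in num], [RatioTerm(r) for r in den]
    )


_ECOLI_RATIOS = {
    # fraction of glucose-6-phosphate catabolized via upper glycolysis
    "glycolysis_vs_ppp": (["pgi"], ["pgi", "zwf"]),
    # fraction of pyruvate made by the Entner-Doudoroff pathway
    "pyr_from_ed": (["eda"], ["pyk", "eda", "mae"]),
    # fraction of PEP made gluconeogenically from oxaloacetate
    "pep_from_gluconeogenesis": (["pck"], ["pck", "eno"]),
    # fraction of pyruvate made by the malic enzyme
    "pyr_from_malic_enzyme": (["mae"], ["pyk", "eda", "mae"]),
    # fraction of oxaloacetate made by anaplerosis from PEP
    "oaa_from_pep": (["ppc"], ["ppc", "mdh"]),
    # three-way origin of the oxaloacetate pool (PEP / TCA / glyoxylate
    # shunt): malate reaching oxaloacetate is attributed to its sources
    "oaa_from_glyoxylate": (["mas"], ["ppc", "fum", "mas"]),
    "oaa_from_tca": (["fum"], ["ppc", "fum", "mas"]),
}

_BSUBTILIS_RATIOS = {
    "glycolysis_vs_ppp": (["pgi"], ["pgi", "zwf"]),
    "pep_from_gluconeogenesis": (["pck"], ["pck", "eno"]),
    "pyr_from_malic_enzyme": (["mae"], ["pyk", "mae"]),
    # anaplerosis is via pyruvate carboxylase in B. subtilis
    "oaa_from_pyr": (["pyc"], ["pyc", "mdh"]),
}

_MODELS = {
    "ecoli_ccm": ("ecoli_ccm.txt", _ECOLI_RATIOS),
    "bsubtilis_ccm": ("bsubtilis_ccm.txt", _BSUBTILIS_RATIOS),
}


@dataclass
class ReferenceModel:
    name: str
    network: MetabolicNetwork
    ratio_defs: dict[str, RatioDefinition]
    specs: dict[str, MeasurementSpec]

    def ratio(self, name: str) -> RatioDefinition:
        if name not in self.ratio_defs:
            raise FluxForestError(
                f"model '{self.name}' has no ratio '{name}'; "
                f"available: {sorted(self.ratio_defs)}"
            )
        return self.ratio_defs[name]

    def spec(self, platform: str) -> MeasurementSpec:
        return self.specs[platform]


def load_reference_model(name: str) -> ReferenceModel:
    """Load a bundled central-carbon model with ratios and platform specs."""
    if name not in _MODELS:
        raise FluxForestError(
            f"unknown model '{name}'; available: {sorted(_MODELS)}"
        )
    fname, ratios = _MODELS[name]
    text = (resources.files("fluxforest.models") / fname).read_text()
    network = parse_network(text)
    ratio_defs = {n: _rd(n, num, den) for n, (num, den) in ratios.items()}
    for rd in ratio_defs.values():
        rd.validate(network)
    specs = {p: b(network) for p, b in _PLATFORM_BUILDERS.items()}
    return ReferenceModel(name, network, ratio_defs, specs)
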