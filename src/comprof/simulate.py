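"""Synthetic BN-PAGE complexome experiments with known ground truth.

The generator emulates the structure of a two-genotype complexome-profiling
study: S gel slices, two groups x n biological replicates, protein
complexes whose subunits populate a ladder of assembly states (e.g.
supercomplexes, dimers, monomers, an RC47-like intermediate), group-specific
state occupancies, per-sample global scale offsets, multiplicative
log-normal replicate noise, and detection dropout.

A protein's expected profile in group g is a Gaussian mixture over slice
index k:

    E[x_k] = amplitude * sum_states occupancy_g(state) *
             exp(-(k - center)^2 / (2 * width^2))

Observed intensities multiply the expectation by a per-sample scale factor
and a unit-mean log-normal noise term (sigma_log = sqrt(ln(1 + CV^2))),
then zero cells independently with the dropout probability.  All randomness
flows from the single seed passed to :func:`simulate_experiment`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .core import ComplexomeMatrix, ProteinAnnotation, SampleDesign

__all__ = [
    "AssemblyState", "ProteinTruth", "SyntheticTruth",
    "expected_profile", "simulate_experiment",
    "default_study_scenario", "band_screen_scenario", "null_scenario",
    "truth_from_dict", "truth_frame", "DEFAULT_BAND_WIDTH",
]

# Generator-level default Gaussian band width (slice units) for user-built
# scenarios; study-like scenarios below use sharper bands (see docs).
DEFAULT_BAND_WIDTH = 0.7


@dataclass
class AssemblyState:
    """One assembly state of a complex: a Gaussian band in slice space."""

    name: str
    center_slice: float
    width: float = DEFAULT_BAND_WIDTH
    occupancy: dict[str, float] = field(default_factory=dict)  # group -> multiplier

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("state width must be positive")
        if any(v < 0 for v in self.occupancy.values()):
            raise ValueError("occupancies must be nonnegative")


@dataclass
class ProteinTruth:
    """Ground truth for one simulated protein."""

    protein: str
    amplitude: float
    states: list[AssemblyState]
    complex: str | None = None
    subunit_class: str | None = None
    proteotypic: bool = True
    has_ctp: bool = False
    conserved: bool = False
    role: str = "background"   # member | background | planted_comigration |
                               # planted_band | decoy
    description: str = ""


@dataclass
class SyntheticTruth:
    """Complete recipe for a synthetic experiment; sufficient to recompute
    every expectation exactly."""

    n_slices: int
    groups: list[str]
    proteins: dict[str, ProteinTruth]
    scale: dict[str, float] = field(default_factory=dict)  # sample -> factor
    noise_cv: float = 0.0
    dropout: float = 0.0

    def __post_init__(self):
        if self.noise_cv < 0:
            raise ValueError("noise CV must be >= 0")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout probability must be in [0, 1)")

    def with_role(self, role: str) -> list[str]:
        return [p for p, t in self.proteins.items() if t.role == role]


def expected_profile(truth: SyntheticTruth, protein: str, group: str) -> np.ndarray:
    """Closed-form expected per-slice profile (no noise, no scale)."""
    try:
        pt = truth.proteins[protein]
    except KeyError:
        raise KeyError(f"unknown protein {protein!r}") from None
    k = np.arange(1, truth.n_slices + 1, dtype=float)
    out = np.zeros(truth.n_slices)
    for st in pt.states:
        occ = st.occupancy.get(group, 0.0)
        if occ > 0:
            out += occ * np.exp(-((k - st.center_slice) ** 2) / (2 * st.width ** 2))
    return pt.amplitude * out


def _annotations(truth: SyntheticTruth) -> dict[str, ProteinAnnotation]:
    return {
        p: ProteinAnnotation(
            protein=p, description=t.description or t.role,
            proteotypic=t.proteotypic, has_ctp=t.has_ctp, conserved=t.conserved,
            complex=t.complex, subunit_class=t.subunit_class,
        )
        for p, t in truth.proteins.items()
    }


def simulate_experiment(
    truth: SyntheticTruth,
    design: SampleDesign,
    seed: int,
) -> tuple[ComplexomeMatrix, dict[str, ProteinAnnotation]]:
    """Draw one synthetic experiment.

    ``intensity(p, k, s) = scale(s) * expected(p, k, group(s)) * noise``
    with unit-mean log-normal noise of the truth's CV, then zeroed with the
    dropout probability wherever the expectation is positive.  The same
    seed yields bit-identical output.
    """
    missing = set(g for g in design.groups) - set(truth.groups)
    if missing:
        raise ValueError(f"design groups {sorted(missing)} absent from truth")
    rng = np.random.default_rng(seed)
    proteins = list(truth.proteins)
    S, N = truth.n_slices, len(design.samples)
    values = np.zeros((len(proteins), S, N))

    sigma = float(np.sqrt(np.log1p(truth.noise_cv ** 2)))
    for i, pid in enumerate(proteins):
        per_group = {g: expected_profile(truth, pid, g) for g in design.groups}
        for j, sample in enumerate(design.samples):
            exp_ = per_group[design.group_of[sample]]
            scale = truth.scale.get(sample, 1.0)
            x = scale * exp_
            if sigma > 0:
                x = x * rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma, size=S)
            if truth.dropout > 0:
                drop = (x > 0) & (rng.random(S) < truth.dropout)
                x = np.where(drop, 0.0, x)
            values[i, :, j] = x
    matrix = ComplexomeMatrix(proteins, S, design, values)
    return matrix, _annotations(truth)


# ---------------------------------------------------------------------------
# ready-made scenarios
# ---------------------------------------------------------------------------

# Sharp Gaussian bands for study-like scenarios: with sigma = 0.25 slices
# the bleed between the two closest bands (monomer at 15 vs RC47 at 17) is
# exp(-8) of exp(-32) ~ 1e-14 of the peak, so noiseless band ratios recover
# the planted occupancy multipliers to better than 1e-9.
_STUDY_WIDTH = 0.25

# PSII assembly-state ladder: band slice, wild-type occupancy, and the
# mutant/wild-type multiplier per state (supercomplexes strongly depleted,
# the RC47 intermediate strongly enriched).
_PSII_STATES = (
    ("SC", 4, 1.00, 0.07),
    ("dimer", 10, 0.80, 0.27),
    ("monomer", 15, 0.60, 0.60),
    ("RC47", 17, 0.15, 6.05),
)

_PSII_MEMBERS = (
    ("PsbA", 1.20e6), ("PsbB", 1.00e6), ("PsbC", 0.90e6), ("PsbD", 1.10e6),
    ("PsbE", 0.50e6), ("PsbF", 0.45e6), ("PsbH", 0.30e6), ("PsbL", 0.25e6),
)


def _psii_states(group_a: str, group_b: str) -> list[AssemblyState]:
    return [AssemblyState(name=n, center_slice=c, width=_STUDY_WIDTH,
                          occupancy={group_a: occ, group_b: occ * mult})
            for n, c, occ, mult in _PSII_STATES]


def default_study_scenario(
    noise_cv: float = 0.2,
    dropout: float = 0.05,
    group_a: str = "WT",
    group_b: str = "lpa2",
    n_replicates: int = 3,
    n_slices: int = 36,
) -> tuple[SyntheticTruth, SampleDesign]:
    """The ready-made two-genotype scenario used throughout the test suite.

    36 slices, 3 + 3 replicates.  Contains a PSII-like complex whose four
    assembly states carry mutant/wild-type multipliers 0.07, 0.27, 0.60 and
    6.05; an unchanged complex; a complex increased 1.29-fold; background
    singleton proteins; a planted co-migrating screen candidate with
    correct annotation flags; shifted-peak and flag-failing decoys; and
    three band-17-enriched proteins.  Per-sample scale offsets emulate
    unequal lane loading.
    """
    design = SampleDesign.from_groups({group_a: n_replicates, group_b: n_replicates},
                                      sep="_")
    proteins: dict[str, ProteinTruth] = {}

    psii_states = _psii_states(group_a, group_b)
    for name, amp in _PSII_MEMBERS:
        proteins[name] = ProteinTruth(
            protein=name, amplitude=amp, states=psii_states, complex="PSII",
            subunit_class="core", has_ctp=True, conserved=True, role="member")

    atp_state = [AssemblyState("holo", 8, _STUDY_WIDTH,
                               {group_a: 1.0, group_b: 1.29})]
    for name, amp in (("AtpA", 0.9e6), ("AtpB", 0.85e6), ("ATPC", 0.4e6),
                      ("ATPD", 0.35e6)):
        proteins[name] = ProteinTruth(
            protein=name, amplitude=amp, states=atp_state, complex="ATPase",
            subunit_class="core", has_ctp=True, conserved=True, role="member")

    b6f_state = [AssemblyState("dimer", 12, _STUDY_WIDTH,
                               {group_a: 1.0, group_b: 1.0})]
    for name, amp in (("PetA", 0.7e6), ("PetB", 0.65e6), ("PETC", 0.5e6),
                      ("PetD", 0.3e6)):
        proteins[name] = ProteinTruth(
            protein=name, amplitude=amp, states=b6f_state, complex="Cytb6f",
            subunit_class="core", has_ctp=True, conserved=True, role="member")

    # planted co-migration candidate: shares the PSII ladder exactly
    proteins["CAND1"] = ProteinTruth(
        protein="CAND1", amplitude=0.20e6, states=psii_states,
        has_ctp=True, conserved=True, role="planted_comigration",
        description="planted PSII co-migrating candidate")

    # decoys: shifted peak (>= 5 slices from any PSII band) or failing flags
    shift_state = [AssemblyState("free", 27, _STUDY_WIDTH,
                                 {group_a: 1.0, group_b: 1.0})]
    proteins["DECOY_SHIFT"] = ProteinTruth(
        protein="DECOY_SHIFT", amplitude=0.3e6, states=shift_state,
        has_ctp=True, conserved=True, role="decoy",
        description="shifted-peak decoy")
    proteins["DECOY_NOCTP"] = ProteinTruth(
        protein="DECOY_NOCTP", amplitude=0.3e6, states=psii_states,
        has_ctp=False, conserved=True, role="decoy",
        description="co-migrating but no transit peptide")
    proteins["DECOY_NOCONS"] = ProteinTruth(
        protein="DECOY_NOCONS", amplitude=0.3e6, states=psii_states,
        has_ctp=True, conserved=False, role="decoy",
        description="co-migrating but not conserved")

    # band-17-enriched proteins (RC47 interactors)
    for i in range(1, 4):
        proteins[f"ENR{i}"] = ProteinTruth(
            protein=f"ENR{i}", amplitude=0.25e6,
            states=[AssemblyState("RC47", 17, _STUDY_WIDTH,
                                  {group_a: 0.1, group_b: 1.0})],
            has_ctp=True, conserved=True, role="planted_band",
            description="planted band-17-enriched protein")

    # background singletons scattered along the lane, away from slice 17
    centers = [c for c in range(2, 35, 2) if abs(c - 17) > 1][:15]
    for i, center in enumerate(centers, start=1):
        proteins[f"BG{i:02d}"] = ProteinTruth(
            protein=f"BG{i:02d}", amplitude=(0.1 + 0.05 * i) * 1e6,
            states=[AssemblyState("free", center, _STUDY_WIDTH,
                                  {group_a: 1.0, group_b: 1.0})],
            has_ctp=(i % 2 == 0), conserved=(i % 3 != 0), role="background")

    # non-proteotypic proteins, removed by the filter
    for i in (1, 2):
        proteins[f"NPT{i}"] = ProteinTruth(
            protein=f"NPT{i}", amplitude=0.2e6,
            states=[AssemblyState("free", 20 + 4 * i, _STUDY_WIDTH,
                                  {group_a: 1.0, group_b: 1.0})],
            proteotypic=False, role="background")

    # Balance the expected lane totals of the two groups with a free
    # antenna-protein pool (higher in the mutant when photosystem complexes
    # are depleted, as unassembled antenna accumulates).  Equal totals mirror
    # equal protein loading per lane, the premise of total-ion normalization;
    # without balance the normalization itself would tilt every ratio.
    interim = SyntheticTruth(n_slices=n_slices, groups=[group_a, group_b],
                             proteins=dict(proteins))
    totals = {g: sum(expected_profile(interim, p, g).sum() for p in proteins)
              for g in (group_a, group_b)}
    k = np.arange(1, n_slices + 1, dtype=float)
    pool_center, pool_amp = 30, 1.0e6
    gauss_sum = float(np.exp(-((k - pool_center) ** 2)
                             / (2 * _STUDY_WIDTH ** 2)).sum())
    base = 0.5
    deficit = totals[group_a] - totals[group_b]   # >0 when mutant lane lighter
    occ_a = base + max(0.0, -deficit) / (pool_amp * gauss_sum)
    occ_b = base + max(0.0, deficit) / (pool_amp * gauss_sum)
    proteins["LHCP"] = ProteinTruth(
        protein="LHCP", amplitude=pool_amp,
        states=[AssemblyState("free", pool_center, _STUDY_WIDTH,
                              {group_a: occ_a, group_b: occ_b})],
        has_ctp=True, conserved=True, role="background",
        description="free antenna pool balancing lane totals")

    scale = {f"{group_a}_{r}": f for r, f in zip(range(1, n_replicates + 1),
                                                 (1.00, 1.15, 0.90))}
    scale |= {f"{group_b}_{r}": f for r, f in zip(range(1, n_replicates + 1),
                                                  (1.05, 0.80, 1.20))}
    truth = SyntheticTruth(n_slices=n_slices, groups=[group_a, group_b],
                           proteins=proteins, scale=scale,
                           noise_cv=noise_cv, dropout=dropout)
    return truth, design


def band_screen_scenario(
    n_background: int = 50,
    noise_cv: float = 0.2,
    dropout: float = 0.05,
    group_a: str = "WT",
    group_b: str = "lpa2",
    n_slices: int = 36,
) -> tuple[SyntheticTruth, SampleDesign]:
    """Background singletons plus three planted band-17-enriched proteins.

    Background proteins have equal occupancy in both groups, alternate
    annotation flags, and centers spread along the lane; only the planted
    trio is band-17 enriched with both flags set.
    """
    design = SampleDesign.from_groups({group_a: 3, group_b: 3}, sep="_")
    proteins: dict[str, ProteinTruth] = {}
    for i in range(1, n_background + 1):
        center = 2.0 + (i * 7) % 33          # deterministic scatter over 2..34
        proteins[f"BG{i:02d}"] = ProteinTruth(
            protein=f"BG{i:02d}", amplitude=(0.1 + 0.02 * (i % 10)) * 1e6,
            states=[AssemblyState("free", center, _STUDY_WIDTH,
                                  {group_a: 1.0, group_b: 1.0})],
            has_ctp=(i % 2 == 0), conserved=(i % 3 != 0), role="background")
    for i in range(1, 4):
        proteins[f"ENR{i}"] = ProteinTruth(
            protein=f"ENR{i}", amplitude=0.25e6,
            states=[AssemblyState("RC47", 17, _STUDY_WIDTH,
                                  {group_a: 0.1, group_b: 1.0})],
            has_ctp=True, conserved=True, role="planted_band")
    truth = SyntheticTruth(n_slices=n_slices, groups=[group_a, group_b],
                           proteins=proteins, noise_cv=noise_cv, dropout=dropout)
    return truth, design


def null_scenario(
    n_proteins: int = 2000,
    noise_cv: float = 0.2,
    group_a: str = "WT",
    group_b: str = "lpa2",
    n_slices: int = 36,
) -> tuple[SyntheticTruth, SampleDesign]:
    """Null experiment: every protein has identical expectation in both
    groups (single Gaussian peak, equal occupancy), unit scale factors, no
    dropout — for calibration checks of the abundance test."""
    design = SampleDesign.from_groups({group_a: 3, group_b: 3}, sep="_")
    proteins = {}
    for i in range(n_proteins):
        center = 2.0 + (i % 33)
        proteins[f"N{i:04d}"] = ProteinTruth(
            protein=f"N{i:04d}", amplitude=(0.2 + 0.01 * (i % 50)) * 1e6,
            states=[AssemblyState("free", center, _STUDY_WIDTH,
                                  {group_a: 1.0, group_b: 1.0})],
            role="background")
    truth = SyntheticTruth(n_slices=n_slices, groups=[group_a, group_b],
                           proteins=proteins, noise_cv=noise_cv, dropout=0.0)
    return truth, design


# ---------------------------------------------------------------------------
# scenario files
# ---------------------------------------------------------------------------

def truth_from_dict(spec: dict) -> tuple[SyntheticTruth, SampleDesign]:
    """Build a scenario from a plain mapping (e.g. a parsed YAML file).

    Schema::

        n_slices: 36
        groups: [WT, lpa2]
        replicates: {WT: 3, lpa2: 3}
        noise_cv: 0.2
        dropout: 0.05
        scale: {WT_1: 1.0, ...}        # optional, default 1 per sample
        proteins:
          - protein: PsbA
            amplitude: 1.2e6
            complex: PSII              # optional
            subunit_class: core        # optional
            proteotypic: true          # default true
            has_ctp: true              # default false
            conserved: true            # default false
            states:
              - {name: SC, center: 4, width: 0.25,
                 occupancy: {WT: 1.0, lpa2: 0.07}}
    """
    groups = list(spec["groups"])
    design = SampleDesign.from_groups(
        {g: int(spec["replicates"][g]) for g in groups}, sep="_")
    proteins: dict[str, ProteinTruth] = {}
    for p in spec["proteins"]:
        states = [AssemblyState(
            name=str(st.get("name", "state")),
            center_slice=float(st["center"]),
            width=float(st.get("width", DEFAULT_BAND_WIDTH)),
            occupancy={g: float(v) for g, v in st["occupancy"].items()},
        ) for st in p["states"]]
        pid = str(p["protein"])
        proteins[pid] = ProteinTruth(
            protein=pid, amplitude=float(p["amplitude"]), states=states,
            complex=p.get("complex"), subunit_class=p.get("subunit_class"),
            proteotypic=bool(p.get("proteotypic", True)),
            has_ctp=bool(p.get("has_ctp", False)),
            conserved=bool(p.get("conserved", False)),
            role=str(p.get("role", "background")))
    truth = SyntheticTruth(
        n_slices=int(spec["n_slices"]), groups=groups, proteins=proteins,
        scale={str(s): float(v) for s, v in spec.get("scale", {}).items()},
        noise_cv=float(spec.get("noise_cv", 0.0)),
        dropout=float(spec.get("dropout", 0.0)))
    return truth, design


def truth_frame(truth: SyntheticTruth):
    """Ground truth as a tidy frame, one row per (protein, state)."""
    import pandas as pd

    rows = []
    for pid, pt in truth.proteins.items():
        for st in pt.states:
            row = {"protein": pid, "amplitude": pt.amplitude,
                   "complex": pt.complex or "", "role": pt.role,
                   "state": st.name, "center_slice": st.center_slice,
                   "width": st.width}
            for g in truth.groups:
                row[f"occupancy_{g}"] = st.occupancy.get(g, 0.0)
            rows.append(row)
    return pd.DataFrame(rows)


def study_catalog():
    """Complex catalog matching :func:`default_study_scenario`."""
    from .core import ComplexCatalog

    return ComplexCatalog({
        "PSII": [(name, "core") for name, _ in _PSII_MEMBERS],
        "ATPase": [(n, "core") for n in ("AtpA", "AtpB", "ATPC", "ATPD")],
        "Cytb6f": [(n, "core") for n in ("PetA", "PetB", "PETC", "PetD")],
    })


def study_bands():
    """Band map matching :func:`default_study_scenario`: SC=4, dimer=10,
    monomer=15, RC47=17."""
    from .core import BandMap

    return BandMap({"SC": [4], "dimer": [10], "monomer": [15], "RC47": [17]})
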