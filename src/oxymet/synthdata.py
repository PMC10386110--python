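"""Seeded synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here: LC-MS feature
tables over the three-condition cultivation design (natural aeration C /
elevated oxygen O2 / elevated oxygen+ozone O3, sampled weekly in two
extract fractions), high-GC 16S rRNA weekly sequence series with planted
point substitutions, and DPPH / disk-diffusion plates realising a given
+/- pattern.  Each generator returns its ground truth alongside the data
so every pipeline stage can be scored against the planted answer.

The ``*_study`` presets encode the observed result patterns of the Lake
Baikal actinobacteria oxygen-stress experiment (presence narrated per
condition and week for the named Streptomyces metabolites; the 1-of-89
identified Rhodococcus feature inventory; the two late-week substitutions
in the Rhodococcus 16S series and none in the Streptomyces one; the
antioxidant and antibiotic call grids).  Cells the narrative is silent
about are encoded as absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bioassay import DiskZone, DpphMeasurement
from .features import FeatureRecord, SampleMeta
from .mutscan import RegionMap, SequenceRecord, load_region_map, map_to_regions

__all__ = [
    "SimConfig",
    "PlantedFeature",
    "PlantedSubstitution",
    "FeatureGroundTruth",
    "design_cells",
    "gen_feature_tables",
    "feature_preset",
    "gen_16s_series",
    "sequence_preset",
    "gen_dpph_plates",
    "gen_zone_table",
    "STREPTOMYCES_DPPH_PATTERN",
    "STREPTOMYCES_ZONE_PATTERN",
    "STUDY_WEEKS",
    "FEATURE_CLASSES",
]

#: Assay sampling grid of the study (every other week of the 3-month run).
STUDY_WEEKS = (1, 3, 5, 7, 9, 11)
#: Weekly grid used for the sequencing series.
SEQUENCE_WEEKS = tuple(range(1, 13))

FEATURE_CLASSES = ("constitutive", "experimental_only", "induced", "control_only")

#: Cell key: (condition, week, fraction).
Cell = tuple[str, int, str]


@dataclass(frozen=True)
class SimConfig:
    """All the dials of the generators; the seed fixes every random draw.

    Defaults mirror the study conditions: three aeration regimes, the
    bi-weekly assay grid, two extract fractions, ppm-scale mass error of a
    well-calibrated Q-TOF (sd 2 ppm), small RT jitter on an 18-min
    gradient, and high-GC (70%) 16S sequences.
    """

    seed: int = 0
    strain: str = "synthetic-strain"
    conditions: tuple[str, ...] = ("C", "O2", "O3")
    weeks: tuple[int, ...] = STUDY_WEEKS
    fractions: tuple[str, ...] = ("biomass", "cultural_liquid")
    n_constitutive: int = 10
    n_experimental_only: int = 5
    n_induced: int = 5
    n_control_only: int = 3
    mass_error_sd_ppm: float = 2.0
    rt_jitter_sd_min: float = 0.05
    dropout_prob: float = 0.1
    mass_range: tuple[float, float] = (160.0, 900.0)
    rt_range: tuple[float, float] = (0.5, 17.5)
    gc_content: float = 0.70
    seq_length: int = 1450
    strain_divergence: float = 0.02

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise ValueError("dropout_prob must be in [0, 1]")
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must be in (0, 1)")
        if self.mass_error_sd_ppm < 0 or self.rt_jitter_sd_min < 0:
            raise ValueError("noise scales must be >= 0")
        if not self.conditions or not self.weeks or not self.fractions:
            raise ValueError("empty design")


@dataclass(frozen=True)
class PlantedFeature:
    """A ground-truth molecule: true mass/RT and its intended presence cells."""

    name: str
    mass: float
    rt: float
    presence: frozenset[Cell]
    feature_class: str
    compound: str | None = None  # library identity, when one exists


@dataclass(frozen=True)
class PlantedSubstitution:
    """A ground-truth substitution in one week's sequence (reference coords)."""

    week: int
    position: int
    ref: str
    alt: str
    region: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("planted substitution must change the base")


@dataclass
class FeatureGroundTruth:
    """Planted molecules plus the realised (post-dropout) presence cells."""

    planted: list[PlantedFeature]
    realized: dict[str, set[Cell]] = field(default_factory=dict)

    def by_class(self, feature_class: str) -> list[PlantedFeature]:
        return [p for p in self.planted if p.feature_class == feature_class]


def design_cells(
    conditions: tuple[str, ...],
    weeks: tuple[int, ...],
    fractions: tuple[str, ...],
) -> list[Cell]:
    return [(c, w, f) for c in conditions for w in weeks for f in fractions]


def _class_cells(feature_class: str, cells: list[Cell], rng: np.random.Generator) -> frozenset[Cell]:
    control = [c for c in cells if c[0] == "C"]
    experimental = [c for c in cells if c[0] != "C"]
    if feature_class == "constitutive":
        return frozenset(cells)
    if feature_class == "experimental_only":
        return frozenset(experimental)
    if feature_class == "control_only":
        return frozenset(control)
    if feature_class == "induced":
        # strictly more experimental than control presence, but with enough
        # control cells that dropout cannot plausibly erase them all
        k = max(1, len(control) // 2)
        picked = rng.choice(len(control), size=k, replace=False)
        return frozenset(experimental + [control[i] for i in sorted(picked)])
    raise ValueError(f"unknown feature class {feature_class!r}")


def _draw_masses(k: int, rng: np.random.Generator, config: SimConfig, taken: list[float]) -> list[float]:
    """Uniform masses kept >= 0.1 Da from each other and from ``taken``."""
    out: list[float] = []
    guard = 0
    while len(out) < k:
        m = float(rng.uniform(*config.mass_range))
        if all(abs(m - t) >= 0.1 for t in taken + out):
            out.append(m)
        guard += 1
        if guard > 100000:
            raise RuntimeError("could not place feature masses with the required spacing")
    return out


def gen_feature_tables(
    config: SimConfig,
    planted: list[PlantedFeature] | None = None,
) -> tuple[list[FeatureRecord], FeatureGroundTruth]:
    """Generate an LC-MS feature table with planted presence classes.

    When ``planted`` is None, molecules are drawn per the class counts in
    the config; observed masses are the true mass perturbed by
    multiplicative Gaussian ppm error, RTs are jittered, and each intended
    cell is independently dropped with ``dropout_prob`` (dropout hides
    presence but never invents it).  Deterministic for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    cells = design_cells(config.conditions, config.weeks, config.fractions)
    if not cells:
        raise ValueError("empty design")

    if planted is None:
        counts = {
            "constitutive": config.n_constitutive,
            "experimental_only": config.n_experimental_only,
            "induced": config.n_induced,
            "control_only": config.n_control_only,
        }
        masses = _draw_masses(sum(counts.values()), rng, config, taken=[])
        planted = []
        i = 0
        for feature_class in FEATURE_CLASSES:
            for j in range(counts[feature_class]):
                planted.append(
                    PlantedFeature(
                        name=f"{feature_class}_{j:02d}",
                        mass=masses[i],
                        rt=float(rng.uniform(*config.rt_range)),
                        presence=_class_cells(feature_class, cells, rng),
                        feature_class=feature_class,
                    )
                )
                i += 1

    truth = FeatureGroundTruth(planted=list(planted))
    records: list[FeatureRecord] = []
    for pf in planted:
        realized: set[Cell] = set()
        for cell in sorted(pf.presence, key=lambda c: (c[0], c[1], c[2])):
            if rng.random() < config.dropout_prob:
                continue
            realized.add(cell)
            eps = rng.normal(0.0, config.mass_error_sd_ppm * 1e-6)
            observed_mass = pf.mass * (1.0 + eps)
            observed_rt = float(
                np.clip(
                    pf.rt + rng.normal(0.0, config.rt_jitter_sd_min),
                    *config.rt_range,
                )
            )
            intensity = float(np.exp(rng.normal(np.log(1e6), 1.0)))
            condition, week, fraction = cell
            records.append(
                FeatureRecord(
                    rt_min=observed_rt,
                    neutral_mass=observed_mass,
                    intensity=intensity,
                    sample=SampleMeta(config.strain, condition, week, fraction),
                )
            )
        truth.realized[pf.name] = realized
    return records, truth


# ---------------------------------------------------------------------------
# Study presets: feature tables
# ---------------------------------------------------------------------------

def _cells_for(conditions: list[str], weeks=STUDY_WEEKS, fraction: str = "cultural_liquid",
               drop: list[Cell] | None = None, add: list[Cell] | None = None) -> frozenset[Cell]:
    cells = {(c, w, fraction) for c in conditions for w in weeks}
    for cell in drop or []:
        cells.discard(cell)
    for cell in add or []:
        cells.add(cell)
    return frozenset(cells)


def _streptomyces_study_planted() -> list[PlantedFeature]:
    """The named Streptomyces metabolites with their narrated presence.

    All presence is encoded in the cultural-liquid fraction on the
    bi-weekly grid.  Experimental-only molecules occupy every O2 and O3
    cell; the 707.5335 Da molecule additionally appears once in the
    control at week 3; the unknown 751.3685 Da molecule misses the single
    O3 week-5 cell; the seven induced compounds sit in the 10.6-17 min RT
    window with no control presence.
    """
    expt = ["O2", "O3"]

    def pf(name, mass, rt, presence, feature_class, compound=None):
        return PlantedFeature(name, mass, rt, presence, feature_class, compound)

    return [
        pf("nocardamine", 600.3486, 4.5, _cells_for(expt), "experimental_only",
           "Desferrioxamine E"),
        pf("ferrioxamine_A2", 599.2496, 2.6, _cells_for(expt), "experimental_only",
           "Ferrioxamine A2"),
        pf("unknown_707", 707.5335, 6.9,
           _cells_for(expt, add=[("C", 3, "cultural_liquid")]), "induced"),
        pf("unknown_572", 572.3175, 4.0, _cells_for(expt), "experimental_only"),
        pf("unknown_751", 751.3685, 15.3,
           _cells_for(expt, drop=[("O3", 5, "cultural_liquid")]), "experimental_only"),
        pf("streptomyceamide_B", 264.0747, 10.7, _cells_for(expt), "experimental_only",
           "Streptomyceamide B"),
        pf("arginomycin", 436.2219, 10.8, _cells_for(expt), "experimental_only",
           "Arginomycin"),
        pf("nivelactam", 439.2704, 12.1, _cells_for(expt), "experimental_only",
           "Nivelactam"),
        pf("antimycin_A", 440.3655, 13.7, _cells_for(expt), "experimental_only",
           "Antimycin A"),
        pf("cadinanone", 270.1833, 12.7, _cells_for(expt), "experimental_only",
           "5,10,11-Trihydroxy-3-cadinanone"),
        pf("tridecanone", 212.2139, 14.2, _cells_for(expt), "experimental_only",
           "11-Methyl-2-tridecanone"),
        pf("hexadecanoic_acid", 270.2561, 14.3, _cells_for(expt), "experimental_only",
           "10-Methylhexadecanoic acid"),
    ]


def _rhodococcus_study_planted(rng: np.random.Generator) -> list[PlantedFeature]:
    """An 89-molecule constitutive inventory with exactly one library identity.

    The identified molecule is the indene-propanoic acid at 294.181 Da;
    the other 88 masses are drawn away from every Rhodococcus-source
    library mass so they dereplicate as unknowns.
    """
    from .complib import bundled_library

    library_masses = [rec.monoisotopic_mass for rec in bundled_library()]
    cells = _cells_for(["C", "O2", "O3"])
    planted = [
        PlantedFeature(
            "indene_propanoic_acid", 294.181, 14.4, cells, "constitutive",
            "Octahydro-7a-methyl-1-(1-methyl-2-oxopropyl)-5-oxo-1H-indene-4-propanoic acid",
        )
    ]
    taken = library_masses + [294.181]
    k = 0
    while len(planted) < 89:
        m = float(rng.uniform(160.0, 900.0))
        if all(abs(m - t) >= 0.05 for t in taken):
            rt = float(rng.uniform(0.5, 17.5))
            planted.append(
                PlantedFeature(f"rhodococcus_unknown_{k:02d}", m, rt, cells, "constitutive")
            )
            taken.append(m)
            k += 1
    return planted


def feature_preset(name: str, seed: int = 0) -> tuple[list[FeatureRecord], FeatureGroundTruth, SimConfig]:
    """Named feature-table scenarios.

    ``streptomyces_study``: the twelve named metabolites with narrated
    presence (cultural liquid, bi-weekly grid, no dropout).
    ``rhodococcus_study``: 89 constitutive molecules, one identifiable.
    """
    if name == "streptomyces_study":
        config = SimConfig(
            seed=seed,
            strain="Streptomyces sp. LPB2020M1",
            fractions=("cultural_liquid",),
            dropout_prob=0.0,
        )
        planted = _streptomyces_study_planted()
    elif name == "rhodococcus_study":
        config = SimConfig(
            seed=seed,
            strain="Rhodococcus sp. LPB2020M2",
            fractions=("cultural_liquid",),
            dropout_prob=0.0,
        )
        planted = _rhodococcus_study_planted(np.random.default_rng(seed + 89))
    else:
        raise ValueError(f"unknown feature preset {name!r}")
    records, truth = gen_feature_tables(config, planted=planted)
    return records, truth, config


# ---------------------------------------------------------------------------
# 16S sequence series
# ---------------------------------------------------------------------------

def _random_bases(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(np.array(list("ACGT")), size=n, p=probs)


def gen_16s_series(
    config: SimConfig,
    scenarios: list[tuple[int, int, str, str]] | None = None,
    region_map: RegionMap | None = None,
    weeks: tuple[int, ...] = SEQUENCE_WEEKS,
) -> tuple[SequenceRecord, list[SequenceRecord], list[PlantedSubstitution]]:
    """A synthetic coordinate reference plus a weekly strain series.

    ``scenarios`` is a list of (week, position, ref_base, alt_base) in
    reference coordinates.  The strain baseline differs from the
    coordinate reference by ``strain_divergence`` random substitutions
    (never at scenario positions), and each weekly copy is identical to
    the baseline except for the scenario substitution planted in its
    configured week only.  Returns (reference, series, ground truth).
    """
    scenarios = scenarios or []
    rng = np.random.default_rng(config.seed)
    if region_map is None:
        region_map = load_region_map()
    n = config.seq_length
    for week, pos, ref, alt in scenarios:
        if not (1 <= pos <= n):
            raise ValueError(f"scenario position {pos} outside sequence length {n}")
        if ref == alt:
            raise ValueError("scenario ref and alt base must differ")
        if week not in weeks:
            raise ValueError(f"scenario week {week} not in the series weeks")

    ref_bases = _random_bases(n, config.gc_content, rng)
    scenario_pos = {pos for _, pos, _, _ in scenarios}
    for _, pos, ref, _ in scenarios:
        ref_bases[pos - 1] = ref

    strain_bases = ref_bases.copy()
    n_divergent = int(round(config.strain_divergence * n))
    candidates = np.array([i for i in range(n) if (i + 1) not in scenario_pos])
    if n_divergent > 0:
        picked = rng.choice(candidates, size=n_divergent, replace=False)
        for i in picked:
            current = strain_bases[i]
            options = [b for b in "ACGT" if b != current]
            strain_bases[i] = options[int(rng.integers(len(options)))]

    reference = SequenceRecord(id="coordinate_reference_synthetic", bases="".join(ref_bases))
    series = []
    truth = []
    for week in weeks:
        bases = strain_bases.copy()
        for s_week, pos, ref, alt in scenarios:
            if s_week == week:
                bases[pos - 1] = alt
                truth.append(
                    PlantedSubstitution(
                        week=week, position=pos, ref=ref, alt=alt,
                        region=map_to_regions(pos, region_map, n),
                    )
                )
        series.append(
            SequenceRecord(id=f"{config.strain}_week{week:02d}", bases="".join(bases))
        )
    return reference, series, truth


def sequence_preset(
    name: str, seed: int = 0
) -> tuple[SequenceRecord, list[SequenceRecord], list[PlantedSubstitution]]:
    """Named 16S scenarios.

    ``rhodococcus_o3``: two late-week substitutions under oxygen+ozone —
    a T->G inside the V2 interval at week 10 and a C->T inside V9 at
    week 12 (GC 65%, the Rhodococcus range).
    ``streptomyces``: the same series shape with no substitutions at all
    (GC 70%).
    """
    if name == "rhodococcus_o3":
        config = SimConfig(seed=seed, strain="Rhodococcus sp. LPB2020M2",
                           gc_content=0.65)
        scenarios = [(10, 180, "T", "G"), (12, 1350, "C", "T")]
    elif name == "streptomyces":
        config = SimConfig(seed=seed, strain="Streptomyces sp. LPB2020M1",
                           gc_content=0.70)
        scenarios = []
    else:
        raise ValueError(f"unknown sequence preset {name!r}")
    return gen_16s_series(config, scenarios)


# ---------------------------------------------------------------------------
# Bioassay plates
# ---------------------------------------------------------------------------

#: Antioxidant (DPPH) +/- pattern of the Streptomyces strain: positive in
#: every experimental cell except O3 week 5, and in the control only at
#: week 3 — identical in both extract fractions.
STREPTOMYCES_DPPH_PATTERN: dict[Cell, bool] = {
    (cond, week, fraction): (
        (cond == "O2")
        or (cond == "O3" and week != 5)
        or (cond == "C" and week == 3)
    )
    for cond in ("C", "O2", "O3")
    for week in STUDY_WEEKS
    for fraction in ("biomass", "cultural_liquid")
}

#: Antibiotic (disk-diffusion vs Bacillus subtilis) pattern: cultural
#: liquid positive weeks 5-11 under both experimental conditions and once
#: (week 1) in the control; biomass positive only at O3 week 11.
STREPTOMYCES_ZONE_PATTERN: dict[Cell, bool] = {
    **{
        (cond, week, "cultural_liquid"): (
            (cond in ("O2", "O3") and week >= 5) or (cond == "C" and week == 1)
        )
        for cond in ("C", "O2", "O3")
        for week in STUDY_WEEKS
    },
    **{
        (cond, week, "biomass"): (cond == "O3" and week == 11)
        for cond in ("C", "O2", "O3")
        for week in STUDY_WEEKS
    },
}


def _check_pattern(pattern: dict[Cell, bool], config: SimConfig) -> list[Cell]:
    cells = design_cells(config.conditions, config.weeks, config.fractions)
    missing = [c for c in cells if c not in pattern]
    extra = [c for c in pattern if c not in cells]
    if missing or extra:
        raise ValueError(
            f"pattern/design mismatch: missing {missing[:3]}, extra {extra[:3]}"
        )
    return cells


def gen_dpph_plates(
    config: SimConfig,
    pattern: dict[Cell, bool],
    control_absorbance: float = 0.85,
    threshold: float = 0.2,
) -> list[DpphMeasurement]:
    """Absorbance plate realising a +/- pattern under the default threshold.

    Positive cells draw scavenging fractions in [0.45, 0.75], negative
    cells in [0, 0.08] — both comfortably clear of the call threshold so
    the pattern is reproduced exactly.
    """
    rng = np.random.default_rng(config.seed)
    cells = _check_pattern(pattern, config)
    plates = []
    for cell in cells:
        positive = pattern[cell]
        scavenging = (
            float(rng.uniform(0.45, 0.75)) if positive else float(rng.uniform(0.0, 0.08))
        )
        condition, week, fraction = cell
        plates.append(
            DpphMeasurement(
                sample=SampleMeta(config.strain, condition, week, fraction),
                absorbance_517=control_absorbance * (1.0 - scavenging),
                negative_control_absorbance=control_absorbance,
            )
        )
    return plates


def gen_zone_table(
    config: SimConfig,
    pattern: dict[Cell, bool],
    test_organism: str = "Bacillus subtilis",
) -> list[DiskZone]:
    """Disk-diffusion zones realising a +/- pattern (6 mm disk).

    Positive cells draw integer zone diameters of 8-18 mm (measured to
    the millimetre); negative cells read exactly the disk diameter.
    """
    rng = np.random.default_rng(config.seed)
    cells = _check_pattern(pattern, config)
    zones = []
    for cell in cells:
        condition, week, fraction = cell
        zone_mm = float(rng.integers(8, 19)) if pattern[cell] else 6.0
        zones.append(
            DiskZone(
                sample=SampleMeta(config.strain, condition, week, fraction),
                test_organism=test_organism,
                zone_mm=zone_mm,
            )
        )
    return zones
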