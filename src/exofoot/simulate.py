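"""Synthetic two-platform supernatant-metabolomics data with planted ground truth.

The generator emulates the structure of a paired short-term (suborbital
rocket, ``TEXUS54`` layout) and long-term (ISS, ``CELLBOX`` layout)
macrophage supernatant GC-MS study:

* raw signal for metabolite *m* in biological sample *s* is
  ``gain_platform * (blank_mean[m] + base_net[m] * effect(m, condition(s)))``
  where ``base_net`` is the signed ground-truth net production (+) /
  consumption (-) and effects are multiplicative on the net value (a
  negative effect flips a metabolite between net production and net
  consumption, the "inverted behaviour" seen after blank subtraction);
* metabolites inside a planted cluster block share a per-sample latent
  factor, inducing a controllable pairwise Pearson correlation rho;
* measurement noise is multiplicative log-normal with a configurable
  coefficient of variation (GC-MS intensities are positive and
  heteroscedastic);
* values below the limit of detection (50 RMA units) go missing with a
  configurable probability (missing-not-at-random censoring);
* one leakage outlier sample has all raw values inflated by a global factor.

Identical seeds give bit-identical tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import CONDITIONS, PLATFORMS, RawAbundanceTable, ValidationError

# --- replicate layouts ----------------------------------------------------


@dataclass(frozen=True)
class SampleSpec:
    """One biological sample: its group/condition and replicate structure."""

    sample_id: str
    group: str  # flight | ground
    condition: str  # hypg | ug | longterm | control
    n_tech_reps: int
    compartments: tuple  # of (compartment_id, recovered_volume_ml)


@dataclass(frozen=True)
class PlatformDesign:
    """Measurement layout of one platform run."""

    platform: str
    samples: tuple  # of SampleSpec
    n_blank_reps: int
    blank_volume: float = 1.0

    def __post_init__(self):
        if self.platform not in PLATFORMS:
            raise ValidationError(f"unknown platform {self.platform!r}")
        for s in self.samples:
            if s.condition not in CONDITIONS:
                raise ValidationError(f"unknown condition {s.condition!r}")


def texus54_design() -> PlatformDesign:
    """Suborbital-rocket layout: hypg + ug flight samples, two ground samples, 3 tech reps, 3 blank reps."""
    comp = (("c1", 18.0),)
    return PlatformDesign(
        platform="TEXUS54",
        samples=(
            SampleSpec("TX54-1", "flight", "hypg", 3, comp),
            SampleSpec("TX54-2", "flight", "ug", 3, comp),
            SampleSpec("TX54-3", "ground", "control", 3, comp),
            SampleSpec("TX54-4", "ground", "control", 3, comp),
        ),
        n_blank_reps=3,
    )


def cellbox_design() -> PlatformDesign:
    """ISS layout: 5 flight samples (1 rep), 3 ground samples (2 tech reps), two compartments, 6 blank reps."""
    comp = (("fix", 4.5), ("stab", 1.5))
    flight = tuple(
        SampleSpec(sid, "flight", "longterm", 1, comp)
        for sid in ("FM-001", "FM-002", "FM-004", "FM-005", "FM-006")
    )
    ground = tuple(SampleSpec(f"GM-00{k}", "ground", "control", 2, comp) for k in (2, 3, 4))
    return PlatformDesign(platform="CELLBOX", samples=flight + ground, n_blank_reps=6)


def simple_design(
    platform: str,
    n_flight: int,
    n_ground: int,
    flight_condition: str = "longterm",
    n_tech_reps: int = 1,
    n_blank_reps: int = 3,
    prefix: str = "S",
) -> PlatformDesign:
    """Single-compartment layout with arbitrary group sizes, for calibration experiments."""
    comp = (("c1", 1.0),)
    samples = tuple(
        SampleSpec(f"{prefix}F-{k:03d}", "flight", flight_condition, n_tech_reps, comp)
        for k in range(1, n_flight + 1)
    ) + tuple(
        SampleSpec(f"{prefix}G-{k:03d}", "ground", "control", n_tech_reps, comp)
        for k in range(1, n_ground + 1)
    )
    return PlatformDesign(platform=platform, samples=samples, n_blank_reps=n_blank_reps)


# --- ground truth ---------------------------------------------------------


@dataclass
class SyntheticTruth:
    """Planted structure of a synthetic pair; the recovery target for tests.

    ``metabolite_effects`` maps metabolite -> {condition: multiplicative
    effect on net RMA}; a negative effect flips the sign of the net value.
    ``cluster_blocks`` is a list of (metabolite tuple, target pairwise rho).
    ``outlier_samples`` is a list of (biological sample id, inflation > 1).
    ``platform_gain`` emulates the non-similar scaling of the dimensionless
    RMA values between platforms (undone later by mean scaling).
    """

    seed: int
    panels: dict  # platform -> list of metabolite ids
    blank_means: dict  # metabolite -> float
    base_net: dict  # metabolite -> signed float
    metabolite_effects: dict = field(default_factory=dict)
    cluster_blocks: list = field(default_factory=list)
    outlier_samples: list = field(default_factory=list)
    unannotated: tuple = ()
    noise_cv: float = 0.1
    missing_below_lod_prob: float = 0.8
    block_latent_scale: float = 0.75
    platform_gain: dict = field(default_factory=lambda: {"TEXUS54": 2.5, "CELLBOX": 1.0})
    lod: float = 50.0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        seen = set()
        for ids, rho in self.cluster_blocks:
            ids = set(ids)
            if ids & seen:
                raise ValidationError("cluster blocks must be disjoint")
            seen |= ids
            if not (-1.0 <= rho <= 1.0):
                raise ValidationError(f"block correlation {rho} outside [-1, 1]")
        for sid, factor in self.outlier_samples:
            if factor <= 1:
                raise ValidationError(f"outlier inflation for {sid} must be > 1")
        if not (0.0 <= self.missing_below_lod_prob <= 1.0):
            raise ValidationError("missing_below_lod_prob must lie in [0, 1]")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        known = set(self.blank_means)
        for m in self.metabolite_effects:
            if m not in known:
                raise ValidationError(f"effect refers to unknown metabolite {m!r}")
        for ids, _ in self.cluster_blocks:
            for m in ids:
                if m not in known:
                    raise ValidationError(f"cluster block refers to unknown metabolite {m!r}")

    def effect(self, metabolite: str, condition: str) -> float:
        return self.metabolite_effects.get(metabolite, {}).get(condition, 1.0)

    def expected_fc(self, metabolite: str, condition: str) -> float:
        """Planted fold change (flight net / ground net) for one condition."""
        return self.effect(metabolite, condition)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cluster_blocks"] = [[list(ids), rho] for ids, rho in self.cluster_blocks]
        d["outlier_samples"] = [[sid, f] for sid, f in self.outlier_samples]
        d["unannotated"] = list(self.unannotated)
        return d


# Named metabolites with planted condition effects (multiplicative on net RMA).
# The strong negative effects reproduce the sign-inversion phenomenology of
# supernatant footprinting (net consumption at 1 g flipping to net production
# in flight, and vice versa); unlisted condition -> effect 1.
_NAMED_EFFECTS = {
    # shared panel
    "Ornithine": {"hypg": -60.0, "ug": -41.0, "longterm": 0.2},
    "Glyceric acid": {"hypg": -12.0, "ug": -4.0, "longterm": 0.5},
    "Ketoleucine": {"ug": 2.5, "longterm": 2.5},
    "Threose": {"ug": 1.5, "longterm": 0.4},
    "L-Valine": {"ug": 1.6, "longterm": 0.45},
    "L-Phenylalanine": {"ug": 1.4, "longterm": 0.5},
    "L-Cysteine": {"ug": 1.3, "longterm": 0.45},
    "3-Hydroxybutyric acid": {"hypg": 1.6, "ug": 1.9, "longterm": 0.35},
    "L-Arginine": {"hypg": 2.5, "ug": 2.0, "longterm": 0.9},
    "myo-Inositol": {"hypg": 3.7, "ug": 2.2, "longterm": 0.8},
    "L-Methionine": {"hypg": 2.2, "ug": 1.8, "longterm": 0.5},
    "L-Proline": {"hypg": 2.4, "ug": 2.1, "longterm": 0.45},
    "Glycine": {"ug": 1.8, "longterm": 0.3},
    "L-Aspartic acid": {"hypg": 0.97, "ug": 1.05, "longterm": 1.02},
    "Glucose": {"hypg": 0.6, "ug": 0.4, "longterm": 1.3},
    # TEXUS-54 only
    "2-Hydroxypyridine": {"hypg": -2.0, "ug": -1.5},
    "Beta-Alanine": {"hypg": 0.3, "ug": 0.35},
    "Dihydrouracil": {"hypg": 0.2, "ug": 0.4},
    "Fructose": {"hypg": 0.25, "ug": 0.45},
    # CELLBOX only
    "Rhamnose": {"longterm": 0.05},
    "3-Methyl-2-oxovaleric acid": {"longterm": 2.2},
    "L-alpha-Aminobutyric acid": {"longterm": 4.0},
    "L-Tryptophan": {"longterm": 3.0},
}

_NAMED_BASE_NET = {
    "Ornithine": -2.0,
    "Glyceric acid": 40.0,
    "Ketoleucine": 200.0,
    "Threose": 280.0,
    "L-Valine": 320.0,
    "L-Phenylalanine": 260.0,
    "L-Cysteine": 240.0,
    "3-Hydroxybutyric acid": 300.0,
    "L-Arginine": 350.0,
    "myo-Inositol": 300.0,
    "L-Methionine": 250.0,
    "L-Proline": 300.0,
    "Glycine": 310.0,
    "L-Aspartic acid": 260.0,
    "Glucose": -600.0,
    "2-Hydroxypyridine": 150.0,
    "Beta-Alanine": 200.0,
    "Dihydrouracil": 180.0,
    "Fructose": 220.0,
    "Rhamnose": 400.0,
    "3-Methyl-2-oxovaleric acid": 150.0,
    "L-alpha-Aminobutyric acid": -120.0,
    "L-Tryptophan": 90.0,
}

_SHARED_NAMED = [
    "Ornithine", "Glyceric acid", "Ketoleucine", "Threose", "L-Valine",
    "L-Phenylalanine", "L-Cysteine", "3-Hydroxybutyric acid", "L-Arginine",
    "myo-Inositol", "L-Methionine", "L-Proline", "Glycine", "L-Aspartic acid",
    "Glucose",
]
_TEXUS_NAMED = [
    "2-Hydroxypyridine", "Beta-Alanine", "Dihydrouracil", "Fructose",
    "Nonadecane", "Lactic acid", "Edetic acid", "Oxamide",
]
_CELLBOX_NAMED = [
    "Rhamnose", "3-Methyl-2-oxovaleric acid", "L-alpha-Aminobutyric acid",
    "L-Tryptophan", "Sucrose", "Benzoic acid", "Phosphoric acid", "Diisopropylamine",
]

YELLOW_BLOCK = ("Threose", "L-Valine", "L-Phenylalanine", "L-Cysteine", "3-Hydroxybutyric acid")
PINK_BLOCK = ("L-Arginine", "myo-Inositol", "L-Methionine", "L-Proline")


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of :func:`generate_pair`; defaults are the study conditions."""

    seed: int = 0
    n_texus: int = 63
    n_cellbox: int = 61
    n_overlap: int = 32
    n_unannotated: int = 3  # per platform, within the panel counts
    noise_cv: float = 0.1
    missing_below_lod_prob: float = 0.8
    with_effects: bool = True
    with_blocks: bool = True
    with_outlier: bool = True
    block_rho: float = 0.95
    pink_rho: float = 0.85
    outlier_inflation: float = 3.0
    block_latent_scale: float = 2.0

    def __post_init__(self):
        if self.n_overlap > min(self.n_texus, self.n_cellbox):
            raise ValidationError("overlap larger than a platform panel")


def build_truth(config: GeneratorConfig) -> SyntheticTruth:
    """Construct the planted truth (panels, blanks, net values, effects) for a pair."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 915001]))

    shared = list(_SHARED_NAMED)[: config.n_overlap]
    texus_only = list(_TEXUS_NAMED)[: max(0, config.n_texus - config.n_overlap)]
    cellbox_only = list(_CELLBOX_NAMED)[: max(0, config.n_cellbox - config.n_overlap)]

    shared += [f"SM-{k:03d}" for k in range(len(shared) + 1, config.n_overlap + 1)]

    n_tex_fill = config.n_texus - config.n_overlap - len(texus_only)
    n_cb_fill = config.n_cellbox - config.n_overlap - len(cellbox_only)
    texus_only += [f"TX-{k:03d}" for k in range(1, n_tex_fill + 1)]
    cellbox_only += [f"CB-{k:03d}" for k in range(1, n_cb_fill + 1)]

    unannotated = []
    for pool, tag in ((texus_only, "T"), (cellbox_only, "C")):
        for k in range(config.n_unannotated):
            if len(pool) > k:
                uid = f"UNK-{tag}{k + 1}"
                pool[-(k + 1)] = uid
                unannotated.append(uid)

    all_ids = shared + texus_only + cellbox_only
    blank_means, base_net = {}, {}
    # a few genuinely low-abundance fillers exercise the censoring/imputation path
    low_ids = {m for m in (texus_only + cellbox_only) if m.startswith(("TX-", "CB-"))}
    low_ids = set(sorted(low_ids)[:3])
    for m in all_ids:
        if m in _NAMED_BASE_NET:
            net = _NAMED_BASE_NET[m]
        elif m in low_ids:
            net = float(rng.uniform(8.0, 18.0)) * (1 if rng.random() < 0.5 else -1)
        else:
            net = float(rng.uniform(100.0, 1000.0)) * (1 if rng.random() < 0.6 else -1)
        base_net[m] = net
        max_net = abs(net) * _max_abs_effect(m)
        # blank must cover the deepest plausible consumption (including the
        # 3-sigma swing of a cluster latent) so raw signals stay positive
        latent_allowance = 0.0
        if config.with_blocks and m in set(YELLOW_BLOCK) | set(PINK_BLOCK):
            latent_allowance = 2.0 * config.block_latent_scale * abs(net)
        if net < 0 or _min_effect(m) < 0:
            blank_means[m] = max_net * float(rng.uniform(1.3, 2.0)) + latent_allowance
        elif m in low_ids:
            blank_means[m] = float(rng.uniform(15.0, 25.0))
        else:
            blank_means[m] = float(rng.uniform(80.0, 400.0)) + latent_allowance

    effects = {m: dict(e) for m, e in _NAMED_EFFECTS.items() if m in set(all_ids)} if config.with_effects else {}
    blocks = []
    if config.with_blocks:
        panel_set = set(all_ids)
        blocks = [
            (ids, rho)
            for ids, rho in ((YELLOW_BLOCK, config.block_rho), (PINK_BLOCK, config.pink_rho))
            if all(m in panel_set for m in ids)
        ]
    outliers = [("FM-002", config.outlier_inflation)] if config.with_outlier else []

    return SyntheticTruth(
        seed=int(config.seed),
        panels={"TEXUS54": shared + texus_only, "CELLBOX": shared + cellbox_only},
        blank_means=blank_means,
        base_net=base_net,
        metabolite_effects=effects,
        cluster_blocks=blocks,
        outlier_samples=outliers,
        unannotated=tuple(unannotated),
        noise_cv=config.noise_cv,
        missing_below_lod_prob=config.missing_below_lod_prob,
        block_latent_scale=config.block_latent_scale,
    )


def _max_abs_effect(m: str) -> float:
    eff = _NAMED_EFFECTS.get(m, {})
    return max([1.0] + [abs(v) for v in eff.values()])


def _min_effect(m: str) -> float:
    eff = _NAMED_EFFECTS.get(m, {})
    return min([1.0] + list(eff.values()))


# --- generation -----------------------------------------------------------

_PLATFORM_STREAM = {"TEXUS54": 1, "CELLBOX": 2}


def generate_platform(design: PlatformDesign, truth: SyntheticTruth) -> RawAbundanceTable:
    """Generate one platform's raw abundance table from the planted truth."""
    panel = truth.panels.get(design.platform)
    if panel is None:
        raise ValidationError(f"truth has no panel for platform {design.platform!r}")
    for m in panel:
        if m not in truth.blank_means or m not in truth.base_net:
            raise ValidationError(f"truth lacks parameters for metabolite {m!r}")

    rng = np.random.default_rng(
        np.random.SeedSequence([int(truth.seed), 77100 + _PLATFORM_STREAM[design.platform]])
    )
    n_m = len(panel)
    midx = {m: i for i, m in enumerate(panel)}
    gain = float(truth.platform_gain.get(design.platform, 1.0))

    blank = np.array([truth.blank_means[m] for m in panel], dtype=float)
    base = np.array([truth.base_net[m] for m in panel], dtype=float)

    # per-biological-sample net values (metabolite x sample)
    sample_specs = list(design.samples)
    net = np.empty((n_m, len(sample_specs)), dtype=float)
    for j, spec in enumerate(sample_specs):
        eff = np.array([truth.effect(m, spec.condition) for m in panel])
        net[:, j] = base * eff

    # planted correlation blocks: shared per-sample latent + independent part,
    # scaled to the metabolite's ground-truth net magnitude
    for ids, rho in truth.cluster_blocks:
        members = [m for m in ids if m in midx]
        if not members:
            continue
        rho = float(np.clip(rho, 0.0, 1.0))
        z = rng.standard_normal(len(sample_specs))
        for m in members:
            i = midx[m]
            eps = rng.standard_normal(len(sample_specs))
            amp = truth.block_latent_scale * abs(truth.base_net[m])
            net[i, :] += amp * (np.sqrt(rho) * z + np.sqrt(1.0 - rho) * eps)

    gross = np.clip(blank[:, None] + net, 0.0, None)

    # expand to measurements
    cols, col_meta, col_signal = [], [], []
    for j, spec in enumerate(sample_specs):
        for comp_id, volume in spec.compartments:
            for rep in range(1, spec.n_tech_reps + 1):
                cid = f"{spec.sample_id}_{comp_id}_r{rep}"
                cols.append(cid)
                col_meta.append(
                    (design.platform, "sample", spec.group, spec.condition, spec.sample_id, comp_id, volume, rep)
                )
                col_signal.append(gross[:, j])
    for rep in range(1, design.n_blank_reps + 1):
        cid = f"BLANK_r{rep}"
        cols.append(cid)
        col_meta.append((design.platform, "blank", "none", "none", "BLANK", "c1", design.blank_volume, rep))
        col_signal.append(blank)

    signal = np.column_stack(col_signal) * gain

    if truth.noise_cv > 0:
        sigma = np.sqrt(np.log1p(truth.noise_cv**2))
        noise = np.exp(sigma * rng.standard_normal(signal.shape) - sigma**2 / 2.0)
        signal = signal * noise

    meta = pd.DataFrame(
        col_meta,
        index=pd.Index(cols, name="measurement_id"),
        columns=[
            "platform", "role", "group", "condition",
            "biological_sample_id", "compartment_id", "recovered_volume", "tech_rep_index",
        ],
    )

    for sid, factor in truth.outlier_samples:
        mask = (meta["biological_sample_id"] == sid).to_numpy()
        signal[:, mask] *= float(factor)

    # censoring happens at the platform's own recorded-signal scale
    if truth.missing_below_lod_prob > 0:
        below = signal < truth.lod
        drop = below & (rng.random(signal.shape) < truth.missing_below_lod_prob)
        signal = np.where(drop, np.nan, signal)

    signal = np.clip(signal, 0.0, None)
    values = pd.DataFrame(signal, index=pd.Index(panel, name="metabolite_id"), columns=cols)
    metab = pd.DataFrame(
        {
            "name": panel,
            "annotated": [m not in set(truth.unannotated) for m in panel],
            "excluded_reason": "none",
        },
        index=values.index,
    )
    return RawAbundanceTable(values=values, measurements=meta, metabolites=metab, platform=design.platform)


def generate_pair(config: GeneratorConfig | None = None, **kwargs):
    """Generate the TEXUS54/CELLBOX pair plus its planted truth.

    Returns ``(texus_table, cellbox_table, truth)``.  Keyword arguments
    override :class:`GeneratorConfig` fields.
    """
    if config is None:
        config = GeneratorConfig(**kwargs)
    elif kwargs:
        config = dataclasses.replace(config, **kwargs)
    truth = build_truth(config)
    t_tex = generate_platform(texus54_design(), truth)
    t_cb = generate_platform(cellbox_design(), truth)
    return t_tex, t_cb, truth
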