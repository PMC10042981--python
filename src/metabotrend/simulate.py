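"""Synthetic study generator with known ground truth.

Emulates a multi-variety seasonal harvest design measured on two untargeted
MS platforms: per-variety weekly sampling with biological replicates,
injection batches containing interleaved pooled-QC samples, between-batch
offsets, linear within-batch signal drift, intensity-dependent (left-censored)
missingness, variety baseline offsets, and cluster-structured temporal trends
anchored at each variety's first harvest week.

Every downstream stage of the pipeline (QC correction, spline trend models,
moderated F-tests, network clustering) has a recoverable answer on the output
of this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CULTIVATION_METHODS, AbundanceMatrix, validate_sample_table
from .exceptions import ValidationError

__all__ = [
    "VarietySpec",
    "DesignSpec",
    "GroundTruth",
    "TEMPLATE_SHAPES",
    "default_design_spec",
    "generate_design",
    "generate_trend_templates",
    "generate_ground_truth",
    "simulate_abundances",
    "inject_missingness",
    "simulate_study",
    "make_compound_table",
    "FLAVOUR_PANEL",
]

# Sensory-relevant compounds whose seasonal trends are reported regardless of
# statistical significance: 11 volatiles and 6 non-volatiles.
FLAVOUR_PANEL = (
    "dimethyl sulphide",
    "dimethyl disulphide",
    "methanethiol",
    "methional",
    "hexanal",
    "(E)-2-hexenal",
    "1-octen-3-ol",
    "2,3-octanedione",
    "2-methoxy-3-isopropyl pyrazine",
    "2-methoxy-3-isobutyl pyrazine",
    "2-pentylfuran",
    "asparagusic acid",
    "asparaptine",
    "protodioscin",
    "shatavarin IX",
    "rutin",
    "3-feruloylquinic acid",
)
_FLAVOUR_VOLATILE = FLAVOUR_PANEL[:11]
_FLAVOUR_NONVOLATILE = FLAVOUR_PANEL[11:]


@dataclass(frozen=True)
class VarietySpec:
    """One harvest series: a variety grown under one cultivation method."""

    name: str
    cultivation: str = "open_field"
    first_calendar_week: int = 13
    n_weeks: int = 8

    @property
    def key(self) -> str:
        return f"{self.name}/{self.cultivation}"


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of the harvest / injection design."""

    varieties: tuple[VarietySpec, ...]
    n_replicates: int = 3
    batch_size: int = 32
    n_qc_per_batch: int = 5
    seed: int = 0

    def validate(self) -> "DesignSpec":
        if not self.varieties:
            raise ValidationError("varieties: at least one variety series is required")
        for v in self.varieties:
            if v.cultivation not in CULTIVATION_METHODS:
                raise ValidationError(
                    f"cultivation: {v.cultivation!r} for {v.name!r} not in {CULTIVATION_METHODS}"
                )
            if not 3 <= v.n_weeks <= 8:
                raise ValidationError(f"n_weeks: series {v.key} has {v.n_weeks}; must be in 3..8")
        keys = [v.key for v in self.varieties]
        if len(set(keys)) != len(keys):
            raise ValidationError("varieties: duplicated variety/cultivation series")
        if self.n_replicates < 2:
            raise ValidationError(f"n_replicates: {self.n_replicates} < 2")
        if self.n_qc_per_batch < 2:
            raise ValidationError(f"n_qc_per_batch: {self.n_qc_per_batch} < 2")
        if self.batch_size <= self.n_qc_per_batch:
            raise ValidationError(
                f"batch_size: {self.batch_size} must exceed n_qc_per_batch={self.n_qc_per_batch}"
            )
        return self


def default_design_spec(seed: int = 0) -> DesignSpec:
    """The default 2019-style season: 8 varieties, 10 series, 3 replicates.

    Three series (one late open-field variety and two early mini-tunnel
    varieties) cover the full 8-week harvest window and are the default
    subjects of the trend model; heat-enhanced series (heated field,
    greenhouse) start in early March (calendar week ~10).
    """
    varieties = (
        VarietySpec("Backlim", "open_field", first_calendar_week=19, n_weeks=8),
        VarietySpec("Fortems", "mini_tunnel", first_calendar_week=13, n_weeks=8),
        VarietySpec("Gijnlim", "mini_tunnel", first_calendar_week=14, n_weeks=8),
        VarietySpec("Grolim", "open_field", first_calendar_week=18, n_weeks=4),
        VarietySpec("Avalim", "mini_tunnel", first_calendar_week=14, n_weeks=4),
        VarietySpec("Cumulus", "mini_tunnel", first_calendar_week=15, n_weeks=4),
        VarietySpec("Primems", "mini_tunnel", first_calendar_week=16, n_weeks=3),
        VarietySpec("Tallems", "mini_tunnel", first_calendar_week=17, n_weeks=3),
        VarietySpec("Backlim", "heated_field", first_calendar_week=10, n_weeks=3),
        VarietySpec("Fortems", "greenhouse", first_calendar_week=10, n_weeks=3),
    )
    return DesignSpec(varieties=varieties, seed=seed)


def generate_design(spec: DesignSpec) -> pd.DataFrame:
    """Lay out biological and QC injections into batches.

    Biological samples are assigned to injection slots in a seeded random
    run order (standard practice to decouple the design from drift); QC
    injections are placed at the first and last slot of every batch and
    evenly in between.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    bio_rows = []
    for v in spec.varieties:
        for week in range(1, v.n_weeks + 1):
            for rep in range(1, spec.n_replicates + 1):
                bio_rows.append(
                    {
                        "sample_id": f"{v.name}.{v.cultivation}.w{week}.r{rep}",
                        "variety": v.name,
                        "cultivation": v.cultivation,
                        "harvest_week_index": week,
                        "calendar_week": v.first_calendar_week + week - 1,
                        "replicate": rep,
                    }
                )
    n_bio = len(bio_rows)
    order = rng.permutation(n_bio)
    bio_per_batch = spec.batch_size - spec.n_qc_per_batch
    n_batches = math.ceil(n_bio / bio_per_batch)

    rows = []
    cursor = 0
    for b in range(1, n_batches + 1):
        batch = f"B{b}"
        n_in_batch = min(bio_per_batch, n_bio - cursor)
        size = n_in_batch + spec.n_qc_per_batch
        qc_pos = np.unique(np.round(np.linspace(0, size - 1, spec.n_qc_per_batch)).astype(int))
        qc_i = 0
        for pos in range(size):
            if pos in qc_pos:
                qc_i += 1
                rows.append(
                    {
                        "sample_id": f"QC.{batch}.{qc_i}",
                        "variety": "",
                        "cultivation": "",
                        "harvest_week_index": np.nan,
                        "calendar_week": np.nan,
                        "replicate": np.nan,
                        "batch": batch,
                        "injection_order": pos + 1,
                        "is_qc": True,
                    }
                )
            else:
                row = dict(bio_rows[order[cursor]])
                row.update({"batch": batch, "injection_order": pos + 1, "is_qc": False})
                rows.append(row)
                cursor += 1

    samples = pd.DataFrame(rows)
    samples = samples.astype(
        {
            "harvest_week_index": "Int64",
            "calendar_week": "Int64",
            "replicate": "Int64",
            "is_qc": bool,
        },
        errors="ignore",
    )
    return validate_sample_table(samples)


# ---------------------------------------------------------------------------
# trend templates

def _sstep(t: np.ndarray) -> np.ndarray:
    """Smooth monotone 0->1 ramp (cubic smoothstep)."""
    return 3 * t**2 - 2 * t**3


def _project_to_spline(curves: np.ndarray, df: int = 3) -> np.ndarray:
    """Project per-variety weekly curves onto the anchored natural-spline span.

    True trends are drawn from the same smooth low-dimensional family the
    trend model fits, so a noise-free simulation is exactly recoverable.
    The anchor (curve = 0 at week 1) is preserved by the projection.
    """
    from .splines import natural_spline_basis

    *lead, w = curves.shape
    if w < df + 1:
        return curves
    B = natural_spline_basis(np.arange(1, w + 1, dtype=float), df=df, anchored=True).matrix
    flat = curves.reshape(-1, w)
    coefs, *_ = np.linalg.lstsq(B, flat.T, rcond=None)
    return (B @ coefs).T.reshape(curves.shape)


def _weeks_t(weeks: int) -> np.ndarray:
    return np.linspace(0.0, 1.0, weeks)


def _per_variety(weeks: int, n_varieties: int, builders) -> np.ndarray:
    t = _weeks_t(weeks)
    curves = np.stack([builders[v % len(builders)](t) for v in range(n_varieties)])
    curves[:, 0] = 0.0
    return curves


# Each shape maps to per-variety weekly logFC curves anchored at 0 in week 1.
# The seven non-flat shapes mirror the qualitative cluster repertoire of a
# seasonal metabolome: a strong early-season decrease with a late-variety
# rebound, a single-variety increase, a mid-season peak with late decline,
# a single-variety strong decrease, and three mild (within +/-2 logFC)
# variety-patterned trends.
def _dip(t: np.ndarray) -> np.ndarray:
    """Half-sine hump: 0 at both season ends, 1 mid-season."""
    return np.sin(np.pi * t)


def _late(t: np.ndarray) -> np.ndarray:
    """Slow start, accelerating towards the season end."""
    return t**3


# The per-variety patterns of the seven non-flat shapes were chosen so their
# concatenated curves are mutually weakly (positively) correlated
# (max pairwise r ~ 0.25): strongly positively correlated templates cannot
# be distinguished by a signed correlation network.
TEMPLATE_SHAPES: dict = {
    "flat": lambda w, nv: np.zeros((nv, w)),
    "strong_decrease": lambda w, nv: _per_variety(
        w, nv,
        [lambda t: -5.0 * _sstep(t), lambda t: -4.6 * _sstep(t), lambda t: -5.2 * _sstep(t)],
    ),
    "decrease_late_rebound": lambda w, nv: _per_variety(
        w, nv,
        [lambda t: -5.0 * _sstep(t), lambda t: -4.5 * _sstep(t), lambda t: 1.2 * _sstep(t)],
    ),
    "single_variety_increase": lambda w, nv: _per_variety(
        w, nv,
        [lambda t: 4.2 * (2 * t - t**2), lambda t: -0.4 * _dip(t), lambda t: 0.4 * _dip(t)],
    ),
    "mid_peak": lambda w, nv: _per_variety(
        w, nv,
        [lambda t: 0.0 * t, lambda t: 3.0 * _dip(t), lambda t: 2.6 * _dip(t)],
    ),
    "single_variety_decrease": lambda w, nv: _per_variety(
        w, nv,
        [lambda t: -0.4 * _sstep(t), lambda t: 0.0 * t, lambda t: -4.6 * _sstep(t)],
    ),
    "mild_decrease": lambda w, nv: _per_variety(
        w, nv,
        [lambda t: -1.6 * _late(t), lambda t: -1.4 * _dip(t), lambda t: -1.4 * _dip(t)],
    ),
    "mild_increase": lambda w, nv: _per_variety(
        w, nv,
        [lambda t: 1.6 * _late(t), lambda t: 1.6 * _late(t), lambda t: 1.4 * _dip(t)],
    ),
    "late_increase": lambda w, nv: _per_variety(
        w, nv,
        [lambda t: -0.4 * _sstep(t), lambda t: 4.0 * _late(t), lambda t: 3.6 * _late(t)],
    ),
}

#: the default non-flat shape repertoire, in template-id order 1..7
DEFAULT_SHAPES = (
    "decrease_late_rebound",
    "single_variety_increase",
    "mid_peak",
    "single_variety_decrease",
    "mild_decrease",
    "mild_increase",
    "late_increase",
)


def generate_trend_templates(
    n_templates: int,
    weeks: int,
    shapes=None,
    seed: int = 0,
    n_varieties: int = 3,
    spline_df: int | None = 3,
) -> np.ndarray:
    """Return an (n_templates, n_varieties, weeks) array of true logFC curves.

    ``shapes`` is a sequence of shape labels from :data:`TEMPLATE_SHAPES`
    (cycled if shorter than ``n_templates``); the default repertoire holds
    the seven non-flat shapes. Every curve is smooth and exactly 0 at the
    first week; the repertoire contains shapes reaching |logFC| >= 4 and
    shapes bounded within +/-2.
    """
    if weeks < 3:
        raise ValidationError(f"weeks must be >= 3, got {weeks}")
    if shapes is None:
        shapes = DEFAULT_SHAPES
    unknown = [s for s in shapes if s not in TEMPLATE_SHAPES]
    if unknown:
        raise ValidationError(
            f"unknown template shapes {unknown}; allowed: {sorted(TEMPLATE_SHAPES)}"
        )
    out = np.zeros((n_templates, n_varieties, weeks))
    for i in range(n_templates):
        shape = shapes[i % len(shapes)]
        out[i] = TEMPLATE_SHAPES[shape](weeks, n_varieties)
        if spline_df is not None:
            out[i] = _project_to_spline(out[i], df=spline_df)
    return out


@dataclass
class GroundTruth:
    """Everything needed to score recovery of the simulated signal.

    ``curves[template_id][series_key]`` holds that series' true weekly logFC
    curve (template_id 0 is reserved for flat compounds and stores no entry).
    """

    series: tuple[str, ...]                      # "variety/cultivation" keys
    weeks: dict                                  # series_key -> n_weeks
    template_names: tuple[str, ...]              # names of templates 1..T
    curves: dict                                 # template_id -> {series: np.ndarray}
    template_id: np.ndarray                      # per compound, 0 = flat
    baselines: np.ndarray                        # per compound, log2 units
    variety_offsets: np.ndarray                  # compounds x series, log2 units
    batch_effects: dict                          # batch -> log2 offset
    drift_slopes: dict                           # batch -> log2 / injection
    residual_sd: float = 0.3
    missing_threshold: float | None = None       # log2 intensity; None = no censoring
    missing_steepness: float = 1.5
    compound_ids: tuple[str, ...] = ()

    def true_curve(self, compound: int, series_key: str) -> np.ndarray:
        tid = int(self.template_id[compound])
        w = self.weeks[series_key]
        if tid == 0:
            return np.zeros(w)
        return self.curves[tid][series_key][:w]


def generate_ground_truth(
    design: pd.DataFrame,
    n_compounds: int,
    shapes=DEFAULT_SHAPES,
    flat_fraction: float = 0.45,
    offset_fraction: float = 0.25,
    offset_sd: float = 1.0,
    baseline_mean: float = 14.0,
    baseline_sd: float = 2.5,
    batch_effect_sd: float = 0.5,
    drift_slope_sd: float = 0.02,
    residual_sd: float = 0.3,
    missing_threshold: float | None = None,
    missing_steepness: float = 1.5,
    template_spline_df: int | None = 3,
    seed: int = 0,
    compound_ids=None,
) -> GroundTruth:
    """Draw a complete ground-truth parameter set matched to ``design``.

    Template curves are evaluated on each series' own within-variety week
    axis; a fraction of compounds is flat, the rest are spread evenly over
    ``shapes``. ``offset_fraction`` of compounds carry variety baseline
    offsets (drawn once per compound x series).
    """
    rng = np.random.default_rng(seed)
    bio = design[~design["is_qc"].astype(bool)]
    series_keys = tuple(
        f"{v}/{c}" for v, c in bio[["variety", "cultivation"]].drop_duplicates().itertuples(index=False)
    )
    weeks = {
        f"{v}/{c}": int(g["harvest_week_index"].max())
        for (v, c), g in bio.groupby(["variety", "cultivation"], sort=False)
    }

    unknown = [s for s in shapes if s not in TEMPLATE_SHAPES]
    if unknown:
        raise ValidationError(f"unknown template shapes {unknown}; allowed: {sorted(TEMPLATE_SHAPES)}")
    n_templates = len(shapes)
    curves: dict = {}
    for tid, shape in enumerate(shapes, start=1):
        per_series = {}
        for si, key in enumerate(series_keys):
            w = weeks[key]
            full = TEMPLATE_SHAPES[shape](w, len(series_keys))
            if template_spline_df is not None:
                full = _project_to_spline(full, df=template_spline_df)
            per_series[key] = full[si]
        curves[tid] = per_series

    n_flat = int(round(flat_fraction * n_compounds))
    tids = np.zeros(n_compounds, dtype=int)
    if n_templates > 0 and n_compounds > n_flat:
        tids[n_flat:] = 1 + (np.arange(n_compounds - n_flat) % n_templates)
    rng.shuffle(tids)

    offsets = np.zeros((n_compounds, len(series_keys)))
    has_offset = rng.random(n_compounds) < offset_fraction
    offsets[has_offset] = rng.normal(0.0, offset_sd, size=(has_offset.sum(), len(series_keys)))

    batches = sorted(design["batch"].unique(), key=lambda b: int(str(b).lstrip("B") or 0))
    batch_effects = {b: float(rng.normal(0.0, batch_effect_sd)) for b in batches}
    drift_slopes = {b: float(rng.normal(0.0, drift_slope_sd)) for b in batches}

    if compound_ids is None:
        compound_ids = tuple(f"M{i + 1:04d}" for i in range(n_compounds))

    return GroundTruth(
        series=series_keys,
        weeks=weeks,
        template_names=tuple(shapes),
        curves=curves,
        template_id=tids,
        baselines=rng.normal(baseline_mean, baseline_sd, size=n_compounds),
        variety_offsets=offsets,
        batch_effects=batch_effects,
        drift_slopes=drift_slopes,
        residual_sd=residual_sd,
        missing_threshold=missing_threshold,
        missing_steepness=missing_steepness,
        compound_ids=tuple(compound_ids),
    )


def simulate_abundances(
    design: pd.DataFrame,
    truth: GroundTruth,
    seed: int | None = None,
) -> tuple[AbundanceMatrix, GroundTruth]:
    """Simulate the raw-scale intensity matrix for ``design`` under ``truth``.

    log2 signal = baseline + variety offset + template curve(week)
    + batch effect + drift * (injection order - 1) + N(0, residual sd).
    QC rows carry the pooled mean of the biological log2 signal per compound
    (a pooled aliquot) plus the same batch, drift and noise terms. The
    returned matrix is 2**signal with left-censored missingness applied when
    ``truth.missing_threshold`` is set.
    """
    if seed is None:
        raise ValidationError("seed is required: simulations must be reproducible")
    rng = np.random.default_rng(seed)
    n_compounds = len(truth.template_id)
    series_index = {k: i for i, k in enumerate(truth.series)}

    bio_mask = ~design["is_qc"].astype(bool).to_numpy()
    n_samples = len(design)
    clean = np.zeros((n_samples, n_compounds))

    cell_cache: dict = {}
    for i, row in enumerate(design.itertuples(index=False)):
        if row.is_qc:
            continue
        key = f"{row.variety}/{row.cultivation}"
        week = int(row.harvest_week_index)
        if (key, week) not in cell_cache:
            si = series_index[key]
            base = truth.baselines + truth.variety_offsets[:, si]
            curve_vals = np.array(
                [truth.true_curve(c, key)[week - 1] for c in range(n_compounds)]
            )
            cell_cache[(key, week)] = base + curve_vals
        clean[i] = cell_cache[(key, week)]
    pooled = clean[bio_mask].mean(axis=0)
    clean[~bio_mask] = pooled

    batch_eff = design["batch"].map(truth.batch_effects).to_numpy(dtype=float)
    drift = design["batch"].map(truth.drift_slopes).to_numpy(dtype=float)
    order = design["injection_order"].to_numpy(dtype=float)
    tech = batch_eff + drift * (order - 1.0)

    signal = clean + tech[:, None] + rng.normal(0.0, truth.residual_sd, size=clean.shape)
    data = pd.DataFrame(
        np.exp2(signal), index=pd.Index(design["sample_id"], name="sample_id"),
        columns=pd.Index(truth.compound_ids, name="compound_id"),
    )
    matrix = AbundanceMatrix(data, scale="raw")
    if truth.missing_threshold is not None:
        qc_ids = design.loc[design["is_qc"].astype(bool), "sample_id"].tolist()
        matrix = inject_missingness(
            matrix,
            threshold=truth.missing_threshold,
            steepness=truth.missing_steepness,
            seed=int(rng.integers(2**31 - 1)),
            qc_ids=qc_ids,
        )
    return matrix, truth


def inject_missingness(
    matrix: AbundanceMatrix,
    threshold: float,
    steepness: float,
    seed: int | None = None,
    qc_ids=(),
) -> AbundanceMatrix:
    """Left-censor cells with probability logistic((threshold - log2 x) * steepness).

    Detection in MS data fails preferentially for low-intensity signals, so
    missingness here is intensity-dependent, not completely at random. QC
    rows (``qc_ids``) are exempt: the pooled sample is abundant by design.
    """
    if steepness <= 0:
        raise ValidationError(f"steepness must be positive, got {steepness}")
    if seed is None:
        raise ValidationError("seed is required: simulations must be reproducible")
    rng = np.random.default_rng(seed)
    vals = matrix.data.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log2v = np.log2(vals)
    from scipy.special import expit

    p_missing = expit(steepness * (threshold - log2v))
    drop = rng.random(vals.shape) < p_missing
    if len(qc_ids):
        qc_rows = matrix.data.index.isin(qc_ids)
        drop[qc_rows, :] = False
    out = matrix.data.where(~drop)
    return matrix.with_data(out)


def make_compound_table(
    truth: GroundTruth,
    n_volatile: int | None = None,
    seed: int = 0,
    annotate_flavour: bool = True,
) -> pd.DataFrame:
    """Build a compound metadata table for the simulated matrix.

    The first ``n_volatile`` compounds are labelled GCMS (default: ~29% of
    compounds, the platform ratio of a typical two-platform asparagus study),
    the rest LCMS. When ``annotate_flavour`` is set, the sensory panel names
    are assigned to randomly chosen compounds of the matching platform.
    """
    rng = np.random.default_rng(seed)
    n = len(truth.compound_ids)
    if n_volatile is None:
        n_volatile = int(round(n * 105 / 366))
    platform = np.array(["GCMS"] * n_volatile + ["LCMS"] * (n - n_volatile))
    classes_v = ["aldehyde", "alcohol", "monoterpene", "furan", "pyrazine", "sulphur compound", "benzenoid"]
    classes_n = ["saponin", "flavonoid glycoside", "amino acid", "sugar", "phenolic", "sulphur compound"]
    chem = [
        rng.choice(classes_v) if platform[i] == "GCMS" else rng.choice(classes_n)
        for i in range(n)
    ]
    annotation = [""] * n
    flavour = np.zeros(n, dtype=bool)
    loi = rng.choice([1, 2, 3, 4], size=n, p=[0.15, 0.3, 0.25, 0.3])
    if annotate_flavour:
        vol_idx = rng.choice(np.arange(n_volatile), size=min(len(_FLAVOUR_VOLATILE), n_volatile), replace=False)
        for name, i in zip(_FLAVOUR_VOLATILE, vol_idx):
            annotation[i] = name
            flavour[i] = True
            loi[i] = 1
        nonvol = np.arange(n_volatile, n)
        if len(nonvol):
            nv_idx = rng.choice(nonvol, size=min(len(_FLAVOUR_NONVOLATILE), len(nonvol)), replace=False)
            for name, i in zip(_FLAVOUR_NONVOLATILE, nv_idx):
                annotation[i] = name
                flavour[i] = True
                loi[i] = 2
    return pd.DataFrame(
        {
            "compound_id": list(truth.compound_ids),
            "platform": platform,
            "annotation": annotation,
            "chemical_class": chem,
            "loi": loi.astype(int),
            "flavour_flag": flavour,
        }
    )


def simulate_study(
    spec: DesignSpec | None = None,
    n_compounds: int = 366,
    seed: int = 0,
    missing_threshold: float | None = 11.5,
    residual_sd: float = 0.3,
    **truth_kwargs,
):
    """One-call simulation: design + truth + matrix + compound metadata.

    Returns (samples, compounds, matrix, truth). Defaults emulate the study
    scale: ~366 compounds on two platforms, batches of 32 with 5 QCs, three
    8-week series suitable for trend modelling, intensity-dependent
    missingness that leaves a subset of compounds >=90% missing.
    """
    rng = np.random.default_rng(seed)
    if spec is None:
        spec = default_design_spec(seed=int(rng.integers(2**31 - 1)))
    samples = generate_design(spec)
    truth = generate_ground_truth(
        samples,
        n_compounds,
        residual_sd=residual_sd,
        missing_threshold=missing_threshold,
        seed=int(rng.integers(2**31 - 1)),
        **truth_kwargs,
    )
    matrix, truth = simulate_abundances(samples, truth, seed=int(rng.integers(2**31 - 1)))
    compounds = make_compound_table(truth, seed=int(rng.integers(2**31 - 1)))
    return samples, compounds, matrix, truth
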