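"""Eye-region distance measurement and diagnostic benchmarks.

The screening idea: on an aligned frontal face, pixel distances between
each iris center and fixed periocular reference points (canthi, lid
apices, brow apex) are stable in healthy eyes.  Population intervals for
those distances — and for the left/right asymmetries — act as diagnostic
benchmarks: an individual whose asymmetry falls outside its interval,
with the deviating eye's own distance also abnormal, is flagged as
strabismic (esotropia when the iris deviates toward the nose, exotropia
when away); a reduced iris-to-upper-lid distance (an MRD1 analog)
signals ptosis.

Benchmark construction follows a fixed recipe per measure: single-pass
Tukey outlier exclusion (1.5×IQR fences, linear-interpolation quartiles),
a Shapiro–Wilk normality check, then either a closed-form normal interval
or a seeded bootstrap.  Two interval modes exist: ``ci_mean`` (interval
for the population mean, mean ± z·s/√n) and ``reference_range``
(individual-level interval, mean ± z·s or bootstrap quantiles), the
latter being the mode used for classification.

The benchmark is exposed statsmodels-style: :class:`BenchmarkModel` is
built from a cohort table, ``fit()`` returns :class:`BenchmarkResults`
carrying the intervals, per-measure diagnostics and a ``summary()``
table; classification hangs off the results object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import LandmarkError, LandmarkSet, iris_center

__all__ = [
    "DiagnosticsError",
    "MeasurementSchema",
    "SchemaEntry",
    "EyeMeasurements",
    "measure_distances",
    "resolve_roles",
    "iqr_filter",
    "normality_check",
    "interval_normal",
    "interval_bootstrap",
    "BenchmarkInterval",
    "Benchmark",
    "BenchmarkModel",
    "BenchmarkResults",
    "build_benchmark",
    "classify",
    "DiagnosisResult",
    "PilotStats",
    "margin_of_error",
    "required_sample_size",
    "cohen_kappa",
    "KappaResult",
    "quality_flag",
]

X_ASYM = "x_asymmetry"
Y_ASYM = "y_asymmetry"


class DiagnosticsError(ValueError):
    pass


def _critical_z(level: float, z_policy: str = "exact") -> float:
    if not 0 < level < 1:
        raise DiagnosticsError("confidence level must be in (0, 1)")
    z = stats.norm.ppf((1 + level) / 2)
    if z_policy == "rounded":
        return round(z, 2)  # the conventional two-decimal table value (1.96 at 0.95)
    if z_policy == "exact":
        return float(z)
    raise DiagnosticsError("z_policy must be 'rounded' or 'exact'")


# ---------------------------------------------------------------------------
# Measurement schema and per-face measurement
# ---------------------------------------------------------------------------

ROLES = ("medial_canthus", "lateral_canthus", "upper_lid_apex", "lower_lid_apex", "brow_apex")


@dataclass(frozen=True)
class SchemaEntry:
    name: str
    eye: str  # 'left' | 'right' (image side)
    role: str
    axis: str  # 'x' | 'y'

    def __post_init__(self):
        if self.eye not in ("left", "right"):
            raise DiagnosticsError(f"eye must be 'left' or 'right', got {self.eye!r}")
        if self.role not in ROLES:
            raise DiagnosticsError(f"unknown landmark role {self.role!r}")
        if self.axis not in ("x", "y"):
            raise DiagnosticsError("axis must be 'x' or 'y'")


@dataclass(frozen=True)
class MeasurementSchema:
    """Named iris-to-reference-point distances, per eye and axis.

    The default schema letters the horizontal medial-canthus distances
    A (left eye) and B (right eye), the lateral-canthus distances CD/EF,
    and the vertical iris-to-upper-lid distances GH/IJ; lower-lid and
    brow measures carry descriptive names.  ``asymmetry_pair`` names the
    two measures whose absolute difference is the horizontal asymmetry
    |A−B| used for strabismus screening.
    """

    entries: tuple[SchemaEntry, ...]
    asymmetry_pair: tuple[str, str] = ("A", "B")

    def __post_init__(self):
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise DiagnosticsError("schema measure names must be unique")
        for nm in self.asymmetry_pair:
            if nm not in names:
                raise DiagnosticsError(f"asymmetry measure {nm!r} not in schema")

    @classmethod
    def default(cls) -> "MeasurementSchema":
        return cls(
            entries=(
                SchemaEntry("A", "left", "medial_canthus", "x"),
                SchemaEntry("B", "right", "medial_canthus", "x"),
                SchemaEntry("CD", "left", "lateral_canthus", "x"),
                SchemaEntry("EF", "right", "lateral_canthus", "x"),
                SchemaEntry("GH", "left", "upper_lid_apex", "y"),
                SchemaEntry("IJ", "right", "upper_lid_apex", "y"),
                SchemaEntry("left_lower_lid", "left", "lower_lid_apex", "y"),
                SchemaEntry("right_lower_lid", "right", "lower_lid_apex", "y"),
                SchemaEntry("left_brow", "left", "brow_apex", "y"),
                SchemaEntry("right_brow", "right", "brow_apex", "y"),
            )
        )

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def all_names(self) -> list[str]:
        """Schema measures plus the derived asymmetries."""
        return self.names + [X_ASYM, Y_ASYM]

    def entry(self, name: str) -> SchemaEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise DiagnosticsError(f"no schema measure named {name!r}")

    def measures_for(self, eye: str, role: str) -> list[str]:
        return [e.name for e in self.entries if e.eye == eye and e.role == role]


@dataclass
class EyeMeasurements:
    """Named absolute pixel distances plus the derived asymmetries.

    ``values`` maps schema measure names to non-negative distances;
    ``x_asymmetry`` is |A−B| (left/right horizontal medial-canthus
    difference) and ``y_asymmetry`` the absolute vertical iris-center
    difference between the eyes.
    """

    values: dict[str, float]
    x_asymmetry: float
    y_asymmetry: float

    def __post_init__(self):
        for k, v in self.values.items():
            if v < 0 or not np.isfinite(v):
                raise DiagnosticsError(f"distance {k!r} must be finite and non-negative")
        if self.x_asymmetry < 0 or self.y_asymmetry < 0:
            raise DiagnosticsError("asymmetries must be non-negative")

    def as_dict(self) -> dict[str, float]:
        out = dict(self.values)
        out[X_ASYM] = self.x_asymmetry
        out[Y_ASYM] = self.y_asymmetry
        return out

    def __getitem__(self, name: str) -> float:
        return self.as_dict()[name]


def resolve_roles(landmarks: LandmarkSet, eye_side: str) -> dict[str, int]:
    """Resolve anatomical roles to landmark indices geometrically.

    Assumes an approximately aligned (roll-corrected) frontal face: the
    medial canthus is the eyelid point nearest the facial midline, the
    lateral canthus the farthest, the lid apices the vertical extremes of
    the eyelid contour, and the brow apex the highest brow point.
    """
    side = eye_side.upper()
    midline_x = (iris_center(landmarks, "left")[0] + iris_center(landmarks, "right")[0]) / 2
    lid_idx = landmarks.groups[f"{side}_EYELID"]
    lid = landmarks.points[lid_idx]
    brow_idx = landmarks.groups[f"{side}_BROW"]
    brow = landmarks.points[brow_idx]
    return {
        "medial_canthus": int(lid_idx[np.argmin(np.abs(lid[:, 0] - midline_x))]),
        "lateral_canthus": int(lid_idx[np.argmax(np.abs(lid[:, 0] - midline_x))]),
        "upper_lid_apex": int(lid_idx[np.argmin(lid[:, 1])]),
        "lower_lid_apex": int(lid_idx[np.argmax(lid[:, 1])]),
        "brow_apex": int(brow_idx[np.argmin(brow[:, 1])]),
    }


def measure_distances(
    landmarks: LandmarkSet, schema: MeasurementSchema | None = None
) -> EyeMeasurements:
    """Absolute per-axis pixel distances from each iris center to the
    schema reference points, plus the derived left/right asymmetries."""
    schema = schema or MeasurementSchema.default()
    centers = {side: iris_center(landmarks, side) for side in ("left", "right")}
    roles = {side: resolve_roles(landmarks, side) for side in ("left", "right")}
    values: dict[str, float] = {}
    for e in schema.entries:
        try:
            idx = roles[e.eye][e.role]
        except KeyError as exc:  # pragma: no cover - roles covers all ROLES
            raise DiagnosticsError(f"unresolvable role {e.role!r} for {e.eye} eye") from exc
        ref = landmarks.points[idx]
        ax = 0 if e.axis == "x" else 1
        values[e.name] = float(abs(centers[e.eye][ax] - ref[ax]))
    a, b = schema.asymmetry_pair
    x_asym = abs(values[a] - values[b])
    y_asym = float(abs(centers["left"][1] - centers["right"][1]))
    return EyeMeasurements(values=values, x_asymmetry=x_asym, y_asymmetry=y_asym)


# ---------------------------------------------------------------------------
# Filtering, normality, intervals
# ---------------------------------------------------------------------------

def iqr_filter(samples, k: float = 1.5) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass Tukey outlier exclusion.

    Quartiles by linear interpolation between order statistics; keeps
    values in [Q1 − k·IQR, Q3 + k·IQR] (bounds inclusive).  Returns the
    kept values (original order) and the indices of the excluded points.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if len(x) < 4:
        raise DiagnosticsError("iqr_filter needs at least 4 samples")
    q1, q3 = np.quantile(x, [0.25, 0.75])  # 'linear' interpolation
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    keep = (x >= lo) & (x <= hi)
    return x[keep], np.flatnonzero(~keep)


def normality_check(samples, alpha: float = 0.05) -> str:
    """Shapiro–Wilk test: returns ``"normal"`` when p ≥ alpha.

    A constant sample is reported ``"non_normal"`` (the test statistic is
    undefined there; the downstream bootstrap degenerates gracefully).
    """
    x = np.asarray(samples, dtype=float).ravel()
    if len(x) < 8:
        raise DiagnosticsError("normality_check needs at least 8 samples")
    if np.ptp(x) == 0:
        return "non_normal"
    _, p = stats.shapiro(x)
    return "normal" if p >= alpha else "non_normal"


@dataclass(frozen=True)
class BenchmarkInterval:
    """A per-measure benchmark interval.

    ``mode="ci_mean"`` is an interval for the cohort mean; the
    ``"reference_range"`` mode is the individual-level interval used for
    classification.  ``n_used`` is the sample size after outlier removal.
    """

    lower: float
    upper: float
    method: str  # 'normal' | 'bootstrap'
    mode: str  # 'ci_mean' | 'reference_range'
    n_used: int
    level: float = 0.95

    def __post_init__(self):
        if self.lower > self.upper + 1e-12:
            raise DiagnosticsError("interval lower bound exceeds upper bound")
        if self.n_used < 2:
            raise DiagnosticsError("interval needs n_used >= 2")

    @property
    def midpoint(self) -> float:
        return (self.lower + self.upper) / 2

    @property
    def half_width(self) -> float:
        return (self.upper - self.lower) / 2

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper


def interval_normal(samples, level: float = 0.95, mode: str = "reference_range") -> BenchmarkInterval:
    """Normal-theory interval: mean ± z·s/√n (``ci_mean``) or mean ± z·s
    (``reference_range``), with the exact standard-normal quantile."""
    x = np.asarray(samples, dtype=float).ravel()
    if len(x) < 2:
        raise DiagnosticsError("interval_normal needs at least 2 samples")
    if mode not in ("ci_mean", "reference_range"):
        raise DiagnosticsError("mode must be 'ci_mean' or 'reference_range'")
    m = float(x.mean())
    s = float(x.std(ddof=1))
    z = _critical_z(level, "exact")
    half = z * s / np.sqrt(len(x)) if mode == "ci_mean" else z * s
    return BenchmarkInterval(m - half, m + half, "normal", mode, len(x), level)


def interval_bootstrap(
    samples,
    level: float = 0.95,
    B: int = 2000,
    seed: int | None = None,
    mode: str = "reference_range",
) -> BenchmarkInterval:
    """Seeded bootstrap interval.

    ``ci_mean``: percentile bootstrap of the sample mean.
    ``reference_range``: bootstrap estimate of the population quantiles —
    the (1±level)/2 empirical quantiles of each resample, averaged over
    resamples.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if len(x) < 8:
        raise DiagnosticsError("interval_bootstrap needs at least 8 samples")
    if B < 200:
        raise DiagnosticsError("bootstrap needs B >= 200")
    if seed is None:
        raise DiagnosticsError("interval_bootstrap requires a seed for reproducibility")
    if mode not in ("ci_mean", "reference_range"):
        raise DiagnosticsError("mode must be 'ci_mean' or 'reference_range'")
    rng = np.random.default_rng(seed)
    lo_p, hi_p = (1 - level) / 2, (1 + level) / 2
    idx = rng.integers(0, len(x), size=(B, len(x)))
    resamples = x[idx]
    if mode == "ci_mean":
        means = resamples.mean(axis=1)
        lo, hi = np.quantile(means, [lo_p, hi_p])
    else:
        qs = np.quantile(resamples, [lo_p, hi_p], axis=1)
        lo, hi = qs[0].mean(), qs[1].mean()
    return BenchmarkInterval(float(lo), float(hi), "bootstrap", mode, len(x), level)


# ---------------------------------------------------------------------------
# Benchmark model (statsmodels-style)
# ---------------------------------------------------------------------------

@dataclass
class Benchmark:
    """Map measure-name → interval plus build metadata."""

    intervals: dict[str, BenchmarkInterval]
    schema: MeasurementSchema
    mode: str
    level: float
    seed: int | None
    bootstrap_B: int

    def __post_init__(self):
        missing = [m for m in self.schema.all_names if m not in self.intervals]
        if missing:
            raise DiagnosticsError(f"benchmark is missing measures: {missing}")

    def __getitem__(self, name: str) -> BenchmarkInterval:
        try:
            return self.intervals[name]
        except KeyError as exc:
            raise DiagnosticsError(f"benchmark has no measure {name!r}") from exc

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "level": self.level,
            "seed": self.seed,
            "bootstrap_B": self.bootstrap_B,
            "schema": [
                {"name": e.name, "eye": e.eye, "role": e.role, "axis": e.axis}
                for e in self.schema.entries
            ],
            "asymmetry_pair": list(self.schema.asymmetry_pair),
            "intervals": {
                k: {
                    "lower": iv.lower,
                    "upper": iv.upper,
                    "method": iv.method,
                    "mode": iv.mode,
                    "n_used": iv.n_used,
                    "level": iv.level,
                }
                for k, iv in self.intervals.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "Benchmark":
        schema = MeasurementSchema(
            entries=tuple(SchemaEntry(**e) for e in data["schema"]),
            asymmetry_pair=tuple(data["asymmetry_pair"]),
        )
        intervals = {k: BenchmarkInterval(**v) for k, v in data["intervals"].items()}
        return cls(
            intervals=intervals,
            schema=schema,
            mode=data["mode"],
            level=data["level"],
            seed=data["seed"],
            bootstrap_B=data["bootstrap_B"],
        )

    @classmethod
    def from_json(cls, path) -> "Benchmark":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


class BenchmarkModel:
    """Benchmark-construction model over a cohort measurement table.

    Parameters
    ----------
    data
        DataFrame with one row per subject and one column per measure
        (all schema names plus ``x_asymmetry`` and ``y_asymmetry``).
    mode
        ``"reference_range"`` (default, individual-level intervals used
        for classification) or ``"ci_mean"``.
    level
        Confidence/coverage level of the intervals.
    iqr_k
        Tukey fence multiple for the single-pass outlier exclusion.
    bootstrap_B
        Number of bootstrap resamples for non-normal measures.
    min_required
        Minimum cohort size; when a pilot-based required sample size is
        known, pass it here (the fit refuses smaller cohorts).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        schema: MeasurementSchema | None = None,
        mode: str = "reference_range",
        level: float = 0.95,
        iqr_k: float = 1.5,
        bootstrap_B: int = 2000,
        min_required: int | None = None,
    ):
        self.schema = schema or MeasurementSchema.default()
        self.mode = mode
        self.level = level
        self.iqr_k = iqr_k
        self.bootstrap_B = bootstrap_B
        missing = [m for m in self.schema.all_names if m not in data.columns]
        if missing:
            raise DiagnosticsError(f"cohort table is missing measures: {missing}")
        required = max(8, min_required or 0)
        if len(data) < required:
            raise DiagnosticsError(
                f"cohort size {len(data)} below required minimum {required}"
            )
        self.data = data[self.schema.all_names].astype(float).reset_index(drop=True)

    @classmethod
    def from_measurements(
        cls, cohort: Sequence[EyeMeasurements], schema: MeasurementSchema | None = None, **kw
    ) -> "BenchmarkModel":
        df = pd.DataFrame([m.as_dict() for m in cohort])
        return cls(df, schema=schema, **kw)

    @classmethod
    def from_csv(cls, path, schema: MeasurementSchema | None = None, **kw) -> "BenchmarkModel":
        return cls(pd.read_csv(path), schema=schema, **kw)

    def fit(self, seed: int | None = 0) -> "BenchmarkResults":
        """Build all per-measure intervals (IQR filter → normality check →
        normal or bootstrap interval)."""
        intervals: dict[str, BenchmarkInterval] = {}
        normality: dict[str, str] = {}
        outliers: dict[str, np.ndarray] = {}
        for i, name in enumerate(self.schema.all_names):
            x = self.data[name].to_numpy()
            kept, out_idx = iqr_filter(x, self.iqr_k)
            if len(kept) < 8:
                raise DiagnosticsError(
                    f"measure {name!r} has fewer than 8 samples after outlier removal"
                )
            verdict = normality_check(kept)
            normality[name] = verdict
            outliers[name] = out_idx
            if verdict == "normal":
                intervals[name] = interval_normal(kept, self.level, self.mode)
            else:
                # derived per-measure seed keeps measures independent yet reproducible
                sub_seed = None if seed is None else (int(seed) * 1000 + i) % (2**31 - 1)
                intervals[name] = interval_bootstrap(
                    kept, self.level, self.bootstrap_B, sub_seed, self.mode
                )
        benchmark = Benchmark(
            intervals=intervals,
            schema=self.schema,
            mode=self.mode,
            level=self.level,
            seed=seed,
            bootstrap_B=self.bootstrap_B,
        )
        return BenchmarkResults(self, benchmark, normality, outliers)


class BenchmarkResults:
    """Fitted diagnostic benchmarks with per-measure diagnostics."""

    def __init__(
        self,
        model: BenchmarkModel,
        benchmark: Benchmark,
        normality: dict[str, str],
        outliers: dict[str, np.ndarray],
    ):
        self.model = model
        self.benchmark = benchmark
        self.normality = normality
        self.outliers = outliers

    @property
    def intervals(self) -> dict[str, BenchmarkInterval]:
        return self.benchmark.intervals

    def n_used(self, name: str) -> int:
        return self.benchmark[name].n_used

    def summary(self) -> str:
        rows = []
        for name, iv in self.benchmark.intervals.items():
            rows.append(
                {
                    "measure": name,
                    "lower": round(iv.lower, 3),
                    "upper": round(iv.upper, 3),
                    "method": iv.method,
                    "normality": self.normality[name],
                    "n_used": iv.n_used,
                    "n_outliers": len(self.outliers[name]),
                }
            )
        df = pd.DataFrame(rows)
        header = (
            f"Eye-distance benchmark ({self.benchmark.mode}, "
            f"level={self.benchmark.level:g}, n={len(self.model.data)})"
        )
        return header + "\n" + df.to_string(index=False)

    def classify(self, m: EyeMeasurements, **kw) -> "DiagnosisResult":
        return classify(m, self.benchmark, **kw)


def build_benchmark(
    cohort: Sequence[EyeMeasurements],
    schema: MeasurementSchema | None = None,
    mode: str = "reference_range",
    level: float = 0.95,
    iqr_k: float = 1.5,
    bootstrap_B: int = 2000,
    seed: int | None = 0,
    min_required: int | None = None,
) -> Benchmark:
    """Functional wrapper: fit a :class:`BenchmarkModel` and return the
    plain :class:`Benchmark`."""
    model = BenchmarkModel.from_measurements(
        cohort,
        schema=schema,
        mode=mode,
        level=level,
        iqr_k=iqr_k,
        bootstrap_B=bootstrap_B,
        min_required=min_required,
    )
    return model.fit(seed=seed).benchmark


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

LABELS = ("normal", "esotropia", "exotropia", "vertical_strabismus", "ptosis")


@dataclass
class DiagnosisResult:
    """Per-eye primary label plus a secondary ptosis flag and quality gate.

    Eyes are keyed by image side ('left' = smaller x); use
    :meth:`relabel` to report anatomically (frontal photo: anatomical
    left = image right).
    """

    labels: dict[str, str]
    ptosis_secondary: dict[str, bool]
    quality_flag: bool = False
    quality_reason: str = ""

    def __post_init__(self):
        for side in ("left", "right"):
            if self.labels.get(side) not in LABELS:
                raise DiagnosticsError(f"invalid label for {side} eye: {self.labels.get(side)!r}")

    def relabel(self, laterality: str = "anatomical") -> dict[str, str]:
        """Labels keyed by the requested laterality convention."""
        if laterality == "image":
            return dict(self.labels)
        if laterality == "anatomical":
            return {"left": self.labels["right"], "right": self.labels["left"]}
        raise DiagnosticsError("laterality must be 'anatomical' or 'image'")

    def to_dict(self, laterality: str = "image") -> dict:
        labels = self.relabel(laterality)
        ptosis = (
            dict(self.ptosis_secondary)
            if laterality == "image"
            else {"left": self.ptosis_secondary["right"], "right": self.ptosis_secondary["left"]}
        )
        return {
            "laterality": laterality,
            "labels": labels,
            "ptosis_secondary": ptosis,
            "quality_flag": self.quality_flag,
            "quality_reason": self.quality_reason,
        }


def _deviation(iv: BenchmarkInterval, x: float) -> float:
    """Deviation from the interval midpoint in half-width units."""
    hw = max(iv.half_width, 1e-12)
    return (x - iv.midpoint) / hw


def classify(
    m: EyeMeasurements,
    b: Benchmark,
    nasal_direction: str = "medial",
) -> DiagnosisResult:
    """Classify one face's measurements against the benchmark.

    Strabismus requires a double gate: the left/right asymmetry must
    exceed the upper bound of its benchmark interval (asymmetries are
    folded magnitudes, so only large values are abnormal) *and* the
    deviating eye's own distance must be outside its two-sided interval;
    the double gate controls false positives under individual-level
    (reference-range) intervals.  The deviating eye is
    the one whose distance departs more from its interval midpoint.  With
    the default medial-canthus schema (``nasal_direction="medial"``) a
    reduced medial distance means nasal deviation → esotropia; a schema
    measured from the lateral canthus would pass ``"lateral"`` to flip
    the sign.  Ptosis is one-sided: an iris-to-upper-lid distance below
    its interval's lower bound.
    """
    if nasal_direction not in ("medial", "lateral"):
        raise DiagnosticsError("nasal_direction must be 'medial' or 'lateral'")
    schema = b.schema
    labels = {"left": "normal", "right": "normal"}
    ptosis_flag = {"left": False, "right": False}

    # horizontal strabismus via |A−B|
    a_name, b_name = schema.asymmetry_pair
    pair = {"left": a_name, "right": b_name}
    if schema.entry(a_name).eye != "left":
        pair = {"left": b_name, "right": a_name}
    if m.x_asymmetry > b[X_ASYM].upper:
        devs = {side: _deviation(b[pair[side]], m[pair[side]]) for side in pair}
        side = max(devs, key=lambda s: abs(devs[s]))
        if not b[pair[side]].contains(m[pair[side]]):
            nasal_is_smaller = nasal_direction == "medial"
            deviated_nasal = (devs[side] < 0) == nasal_is_smaller
            labels[side] = "esotropia" if deviated_nasal else "exotropia"

    # vertical strabismus via iris-center y difference
    upper = {"left": None, "right": None}
    for side in upper:
        names = schema.measures_for(side, "upper_lid_apex")
        upper[side] = names[0] if names else None
    if m.y_asymmetry > b[Y_ASYM].upper and all(upper.values()):
        devs = {side: _deviation(b[upper[side]], m[upper[side]]) for side in upper}
        side = max(devs, key=lambda s: abs(devs[s]))
        # a displaced iris shifts both lid distances; isolated upper-lid
        # reduction is ptosis, not vertical deviation
        lower_names = schema.measures_for(side, "lower_lid_apex")
        lower_ok = not lower_names or not b[lower_names[0]].contains(m[lower_names[0]])
        if (
            labels[side] == "normal"
            and not b[upper[side]].contains(m[upper[side]])
            and lower_ok
        ):
            labels[side] = "vertical_strabismus"

    # ptosis: reduced iris-to-upper-lid distance (MRD1 analog), one-sided
    for side in ("left", "right"):
        name = upper[side]
        if name is None:
            continue
        if m[name] < b[name].lower:
            if labels[side] == "normal":
                labels[side] = "ptosis"
            else:
                ptosis_flag[side] = True

    return DiagnosisResult(labels=labels, ptosis_secondary=ptosis_flag)


# ---------------------------------------------------------------------------
# Pilot statistics: margin of error and required sample size
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PilotStats:
    """Pilot-study summary for sample-size planning."""

    sigma_pilot: float
    n_pilot: int
    level: float = 0.95

    def __post_init__(self):
        if self.sigma_pilot < 0:
            raise DiagnosticsError("sigma_pilot must be non-negative")
        if self.n_pilot < 1:
            raise DiagnosticsError("n_pilot must be at least 1")
        if not 0 < self.level < 1:
            raise DiagnosticsError("level must be in (0, 1)")

    @property
    def margin_of_error(self) -> float:
        return margin_of_error(self.sigma_pilot, self.n_pilot, self.level)


def margin_of_error(
    sigma: float, n: int, level: float = 0.95, z_policy: str = "rounded"
) -> float:
    """Pilot margin of error ``E = z · σ/√n``.

    With the default ``z_policy="rounded"`` the critical value is the
    conventional two-decimal 1.96 at the 0.95 level; ``"exact"`` uses the
    exact quantile 1.959964.
    """
    if n < 1:
        raise DiagnosticsError("n must be at least 1")
    if sigma < 0:
        raise DiagnosticsError("sigma must be non-negative")
    z = _critical_z(level, z_policy)
    return float(z * sigma / np.sqrt(n))


def required_sample_size(
    sigma: float, E: float, level: float = 0.95, z_policy: str = "rounded"
) -> tuple[float, int]:
    """Required sample size ``n = (z·σ/E)²``; returns the real value and
    its ceiling."""
    if E <= 0:
        raise DiagnosticsError("margin of error E must be positive")
    if sigma < 0:
        raise DiagnosticsError("sigma must be non-negative")
    z = _critical_z(level, z_policy)
    n = float((z * sigma / E) ** 2)
    return n, int(np.ceil(n))


# ---------------------------------------------------------------------------
# Inter-rater agreement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KappaResult:
    kappa: float
    p_value: float
    p_observed: float
    p_expected: float
    se0: float
    n: int


def cohen_kappa(table) -> KappaResult:
    """Cohen's kappa on a square rater1×rater2 contingency table.

    κ = (pₒ − pₑ)/(1 − pₑ); the p-value is the two-sided asymptotic
    normal test of κ = 0 using the large-sample null standard error
    (Fleiss, Cohen & Everitt)."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise DiagnosticsError("rater table must be square")
    if t.shape[0] < 2:
        raise DiagnosticsError("rater table needs at least 2 categories")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise DiagnosticsError("rater table must hold non-negative integer counts")
    n = t.sum()
    if n < 2:
        raise DiagnosticsError("rater table needs at least 2 ratings")
    p = t / n
    po = float(np.trace(p))
    rows = p.sum(axis=1)
    cols = p.sum(axis=0)
    pe = float(rows @ cols)
    if pe >= 1 - 1e-12:
        raise DiagnosticsError("chance agreement is 1; kappa is undefined")
    kappa = (po - pe) / (1 - pe)
    var0 = (pe + pe**2 - float(np.sum(rows * cols * (rows + cols)))) / (n * (1 - pe) ** 2)
    se0 = float(np.sqrt(max(var0, 0.0)))
    if se0 > 0:
        z = kappa / se0
        p_value = float(2 * stats.norm.sf(abs(z)))
    else:
        p_value = float(0.0 if kappa != 0 else 1.0)
    return KappaResult(float(kappa), p_value, po, pe, se0, int(n))


# ---------------------------------------------------------------------------
# Quality gate
# ---------------------------------------------------------------------------

def quality_flag(
    landmarks: LandmarkSet,
    roll_max: float = 5.0,
    yaw_ratio_bounds: tuple[float, float] = (0.8, 1.25),
) -> tuple[bool, str]:
    """Flag poor-quality captures by pose.

    Roll: |interocular axis angle| above ``roll_max`` degrees.
    Yaw proxy: the ratio of left/right lateral-canthus-to-iris-midpoint
    horizontal extents outside ``yaw_ratio_bounds`` (a turned head
    foreshortens one half-face).  Returns ``(flagged, reason)``.
    """
    from .geometry import interocular_axis as _axis

    angle = _axis(landmarks)
    if abs(angle) > roll_max:
        return True, f"roll: interocular axis {angle:.1f} deg exceeds {roll_max:g} deg"
    mid_x = (iris_center(landmarks, "left")[0] + iris_center(landmarks, "right")[0]) / 2
    extents = {}
    for side in ("left", "right"):
        idx = resolve_roles(landmarks, side)["lateral_canthus"]
        extents[side] = abs(landmarks.points[idx][0] - mid_x)
    if extents["right"] < 1e-9:
        return True, "yaw: degenerate right half-face extent"
    ratio = extents["left"] / extents["right"]
    lo, hi = yaw_ratio_bounds
    if not lo <= ratio <= hi:
        return True, f"yaw: half-face extent ratio {ratio:.2f} outside [{lo:g}, {hi:g}]"
    return False, ""
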