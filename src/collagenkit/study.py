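"""Cohort-level orchestration: correlations, group contrasts, reports.

Joins per-patient density scores (VAS % area, Volpara % volume) with the
tissue metrics produced by the imaging and mechanics stages, computes the
registered associations (Pearson r-squared with two-sided p from the t
transform) and low/high-density group contrasts (Mann-Whitney U), and
writes a deterministic JSON + CSV report.  A fully synthetic mode builds a
cohort through the package's own generators so the whole pipeline can run
end to end without patient data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field
from scipy import stats

from . import __version__ as _pkg_version
from .forcespec import Cantilever, build_modulus_map, compare_groups, process_curve
from .histoseg import segment_tissue, tissue_fractions
from .orientation import mean_coherency, structure_tensor_field
from .synthetic import (
    FIBRE_CALIBRATION,
    gen_fibre_image,
    gen_force_grid,
    gen_histology,
)

__all__ = ["CohortRecord", "AssociationResult", "correlate", "simulate_cohort",
           "run_study", "StudyReport"]

#: metric names the cohort table may carry
METRIC_REGISTRY = (
    "epithelial_fraction",
    "adipose_fraction",
    "stromal_fraction",
    "psr_periductal_fraction",
    "mean_coherency",
    "modulus_median_kpa",
)


@dataclass(frozen=True)
class CohortRecord:
    """One patient's density scores and derived tissue metrics."""

    patient_id: str
    vas_percent: float
    volpara_percent: float
    group: str | None = None  # "low" | "high" | None (not selected)
    metrics: dict[str, float] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in (("vas_percent", self.vas_percent),
                            ("volpara_percent", self.volpara_percent)):
            if not 0.0 <= value <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100], got {value}")
        unknown = set(self.metrics) - set(METRIC_REGISTRY)
        if unknown:
            raise ValueError(f"unregistered metrics: {sorted(unknown)}")


@dataclass(frozen=True)
class AssociationResult:
    """Pearson association between two per-patient quantities."""

    r_squared: float
    p: float
    n: int
    method: str = "pearson"


def correlate(x, y) -> AssociationResult:
    """Pearson r-squared with two-sided p; missing pairs are dropped.

    Raises
    ------
    ValueError
        For fewer than 3 complete pairs or zero variance on either side.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    return AssociationResult(
        r_squared=float(res.statistic**2), p=float(res.pvalue), n=int(x.size)
    )


# --------------------------------------------------------------------------
# synthetic cohort


def _sub_seed(seed: int, *parts: int) -> int:
    """Derive a stable 31-bit stage seed from the study seed."""
    h = hashlib.sha256(("/".join(map(str, (seed, *parts)))).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def simulate_cohort(
    seed: int,
    n_patients: int = 22,
    n_mechanics: int = 12,
    vas_range: tuple[float, float] = (11.0, 69.0),
    volpara_range: tuple[float, float] = (3.0, 25.0),
    vas_volpara_r2: float = 0.70,
    psr_md_r2: float = 0.8658,
    coherency_by_group: dict[str, float] = None,
    modulus_median_by_group: dict[str, float] = None,
    patient_log_sd: float = 0.4,
    histology_size: int = 128,
    force_grid_n: int = 5,
) -> tuple[list[CohortRecord], dict]:
    """Build a synthetic cohort exercising every analysis stage.

    Volpara scores are drawn uniformly over ``volpara_range``; VAS scores
    and the peri-ductal PSR fraction are planted as linear functions of
    Volpara with Gaussian noise calibrated so the population r-squared
    matches ``vas_volpara_r2`` and ``psr_md_r2``.  Tissue fractions come
    from generated histology images run through the segmentation stage and
    are unrelated to density.  The ``n_mechanics`` patients most extreme
    in Volpara are split into low/high groups; each gets a fibre image
    (coherency target per group) and a force grid whose per-patient median
    modulus is log-normal about the group centre with spread
    ``patient_log_sd``.  Returns the records and a provenance map of the
    per-stage seeds.
    """
    if coherency_by_group is None:
        coherency_by_group = {"low": 0.21, "high": 0.38}
    if modulus_median_by_group is None:
        modulus_median_by_group = {"low": 247.0, "high": 611.0}
    rng = np.random.default_rng(_sub_seed(seed, 0))

    vol = np.sort(rng.uniform(*volpara_range, n_patients))

    def planted_linear(x: np.ndarray, lo: float, hi: float, r2: float) -> np.ndarray:
        span = hi - lo
        signal = lo + (x - x.min()) / np.ptp(x) * span
        noise_sd = np.std(signal) * np.sqrt((1.0 - r2) / r2)
        return signal + rng.normal(0.0, noise_sd, x.size)

    vas = np.clip(planted_linear(vol, *vas_range, vas_volpara_r2), 0.0, 100.0)
    psr = np.clip(planted_linear(vol, 0.05, 0.45, psr_md_r2), 0.0, 1.0)

    half = n_mechanics // 2
    groups: list[str | None] = [None] * n_patients
    for i in range(half):
        groups[i] = "low"
        groups[n_patients - 1 - i] = "high"

    cant = Cantilever(spring_constant=3.0, tip_radius=1.0)
    records: list[CohortRecord] = []
    provenance: dict[str, int] = {"cohort": _sub_seed(seed, 0)}
    for i in range(n_patients):
        pid = f"SIM{i+1:03d}"
        hist_seed = _sub_seed(seed, 1, i)
        provenance[f"histology/{pid}"] = hist_seed
        frac_req = {
            "epithelial": float(rng.uniform(0.01, 0.10)),
            "adipose": float(rng.uniform(0.10, 0.60)),
        }
        frac_req["stromal"] = float(
            max(0.0, min(0.85 - frac_req["adipose"], rng.uniform(0.20, 0.70)))
        )
        image, _, _ = gen_histology(frac_req, image_size=histology_size,
                                    seed=hist_seed)
        fr = tissue_fractions(segment_tissue(image))
        metrics = {
            "epithelial_fraction": fr.epithelial,
            "adipose_fraction": fr.adipose,
            "stromal_fraction": fr.stromal,
            "psr_periductal_fraction": float(psr[i]),
        }

        if groups[i] is not None:
            fib_seed = _sub_seed(seed, 2, i)
            provenance[f"fibres/{pid}"] = fib_seed
            img, _ = gen_fibre_image(coherency_by_group[groups[i]], seed=fib_seed)
            field = structure_tensor_field(
                img, FIBRE_CALIBRATION["sigma_grad"], FIBRE_CALIBRATION["sigma_window"]
            )
            metrics["mean_coherency"] = mean_coherency(
                field, energy_quantile=FIBRE_CALIBRATION["energy_quantile"]
            )

            mech_seed = _sub_seed(seed, 3, i)
            provenance[f"forcegrid/{pid}"] = mech_seed
            centre = modulus_median_by_group[groups[i]] * float(
                rng.lognormal(0.0, patient_log_sd)
            )
            field_kpa = centre * rng.lognormal(
                0.0, 0.3, (force_grid_n, force_grid_n)
            )
            curves, _ = gen_force_grid(field_kpa, cant, seed=mech_seed)
            fits = [process_curve(c, cant, coarse_step=3) for c in curves]
            metrics["modulus_median_kpa"] = build_modulus_map(fits, 25.0).median()

        records.append(
            CohortRecord(
                patient_id=pid,
                vas_percent=float(vas[i]),
                volpara_percent=float(vol[i]),
                group=groups[i],
                metrics=metrics,
            )
        )
    return records, provenance


# --------------------------------------------------------------------------
# report


class AssociationRow(BaseModel):
    x: str
    y: str
    n: int = Field(ge=3)
    r_squared: float = Field(ge=0.0, le=1.0)
    p: float = Field(ge=0.0, le=1.0)
    method: str


class ContrastRow(BaseModel):
    metric: str
    test: str
    n_low: int = Field(ge=2)
    n_high: int = Field(ge=2)
    statistic: float
    p: float = Field(ge=0.0, le=1.0)


class StudyReport(BaseModel):
    """Validated study report: package version, seeds, config hash,
    registered associations and group contrasts, raw p-values with the
    number of tests run (no multiplicity correction is applied)."""

    package_version: str
    seed: int | None
    config_hash: str
    n_patients: int
    n_tests: int
    stage_seeds: dict[str, int]
    associations: list[AssociationRow]
    contrasts: list[ContrastRow]
    notices: list[str]


_ASSOCIATION_PAIRS = [
    ("volpara_percent", "vas_percent"),
    ("volpara_percent", "epithelial_fraction"),
    ("volpara_percent", "adipose_fraction"),
    ("volpara_percent", "stromal_fraction"),
    ("volpara_percent", "psr_periductal_fraction"),
]
_CONTRAST_METRICS = ["mean_coherency", "modulus_median_kpa"]


def cohort_frame(records: list[CohortRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "vas_percent": r.vas_percent,
            "volpara_percent": r.volpara_percent,
            "group": r.group or "",
        }
        row.update({m: r.metrics.get(m, np.nan) for m in METRIC_REGISTRY})
        rows.append(row)
    return pd.DataFrame(rows)


def run_study(config: dict | str | Path) -> StudyReport:
    """Execute the cohort analysis described by a config mapping/YAML path.

    Config keys: ``simulate`` (bool), ``seed`` (int, required when
    simulating), ``cohort_csv`` (path to an existing cohort table,
    alternative to simulation), ``out_dir`` (optional; where report.json
    and cohort.csv are written), plus optional overrides passed through to
    :func:`simulate_cohort`.  Stages whose inputs are missing are skipped
    with an explicit notice in the report.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    # the hash identifies the analysis, not where its output lands
    hashed = {k: v for k, v in config.items() if k != "out_dir"}
    config_hash = hashlib.sha256(
        json.dumps(hashed, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]

    notices: list[str] = []
    stage_seeds: dict[str, int] = {}
    if config.get("simulate"):
        seed = int(config["seed"])
        sim_keys = (
            "n_patients", "n_mechanics", "vas_volpara_r2", "psr_md_r2",
            "patient_log_sd", "histology_size", "force_grid_n",
        )
        overrides = {k: config[k] for k in sim_keys if k in config}
        records, stage_seeds = simulate_cohort(seed, **overrides)
        frame = cohort_frame(records)
    elif config.get("cohort_csv"):
        seed = config.get("seed")
        frame = pd.read_csv(config["cohort_csv"])
    else:
        raise ValueError("config must set simulate: true or name a cohort_csv")

    associations: list[AssociationRow] = []
    for x_name, y_name in _ASSOCIATION_PAIRS:
        if y_name not in frame or frame[y_name].dropna().size < 3:
            notices.append(f"association {x_name}~{y_name} skipped: missing data")
            continue
        res = correlate(frame[x_name], frame[y_name])
        associations.append(
            AssociationRow(x=x_name, y=y_name, n=res.n, r_squared=res.r_squared,
                           p=res.p, method=res.method)
        )

    contrasts: list[ContrastRow] = []
    for metric in _CONTRAST_METRICS:
        if metric not in frame:
            notices.append(f"contrast {metric} skipped: missing column")
            continue
        low = frame.loc[frame["group"] == "low", metric].dropna()
        high = frame.loc[frame["group"] == "high", metric].dropna()
        if len(low) < 2 or len(high) < 2:
            notices.append(f"contrast {metric} skipped: insufficient group sizes")
            continue
        stat, p = compare_groups(low, high, "mann_whitney")
        contrasts.append(
            ContrastRow(metric=metric, test="mann_whitney", n_low=len(low),
                        n_high=len(high), statistic=stat, p=p)
        )

    report = StudyReport(
        package_version=_pkg_version,
        seed=seed,
        config_hash=config_hash,
        n_patients=int(len(frame)),
        n_tests=len(associations) + len(contrasts),
        stage_seeds=stage_seeds,
        associations=associations,
        contrasts=contrasts,
        notices=notices,
    )

    out_dir = config.get("out_dir")
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report.model_dump(), indent=2, sort_keys=True) + "\n"
        )
        frame.to_csv(out / "cohort.csv", index=False)
        (out / "report.schema.json").write_text(
            json.dumps(StudyReport.model_json_schema(), indent=2, sort_keys=True)
            + "\n"
        )
    return report
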