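"""Self-contained synthetic DLBCL cohorts: H&E-like slides with planted
label-discriminative patches, Table-1-like clinical covariates, and
right-censored survival times.

The generator emulates the structure of a lymphoma R/R study without any
real data: slides are white-glass rasters with pink/purple tissue blobs on
a 512-pixel grid; a config-controlled fraction of tissue patches in R/R
(label 1) slides carries a discriminative high-cellularity texture (dark
elliptical nuclei at ``nucleus_density_signal`` vs the background density
elsewhere). Clinical covariates follow a logistic label model expressed
through per-variable log-odds effects; survival is exponential with a
label hazard multiplier and administrative censoring; missingness is MCAR.
Ground-truth signal-patch coordinates are kept alongside each slide so
attention recovery is directly testable.

Identical (config, seed) reproduces cohorts bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.draw import ellipse

from .clinical import VariableSchema
from .encode import EncoderSpec, FeatureBag, encode_slide
from .segment import compute_tissue_mask, extract_patch_grid
from .table1 import reconstruct_table1_fixture  # noqa: F401  (re-export)

__all__ = [
    "SyntheticConfig",
    "CohortRecord",
    "generate_slide",
    "generate_clinical",
    "generate_survival",
    "generate_cohort",
    "build_feature_cohort",
    "FeatureCohort",
    "default_clinical_schema",
    "reconstruct_table1_fixture",
]

PATCH = 512

# Default covariate set mirrors a lymphoma baseline table: at least one
# binary, one multicategory and one continuous variable. "p0" is the
# level-1 probability (or level distribution) in the non-R/R group;
# effects below tilt the R/R group.
DEFAULT_CLINICAL_VARS: dict[str, dict] = {
    "gender": {"kind": "binary", "levels": ["Female", "Male"], "p0": 0.54},
    "age": {"kind": "continuous", "mean": 60.0, "sd": 12.0},
    "tumor_stage": {
        "kind": "multicategory",
        "levels": ["I", "II", "III", "IV"],
        "p0": [0.35, 0.36, 0.17, 0.12],
    },
    "cell_of_origin": {"kind": "binary", "levels": ["GCB", "non-GCB"], "p0": 0.40},
    "ldh_elevated": {"kind": "binary", "levels": ["No", "Yes"], "p0": 0.40},
    "wbc_count": {"kind": "continuous", "mean": 6.5, "sd": 2.4},
    "extranodal_sites": {"kind": "binary", "levels": ["0", ">=1"], "p0": 0.76},
    "ipi_high": {"kind": "binary", "levels": ["0-2", "3-5"], "p0": 0.20},
    "double_expression": {"kind": "binary", "levels": ["No", "Yes"], "p0": 0.17},
}

# log-odds (R/R vs non-R/R) per variable; for continuous variables the
# effect is the log-odds per one SD (realised as a beta*sd mean shift).
DEFAULT_CLINICAL_EFFECTS: dict[str, float] = {
    "gender": 0.3,
    "age": 0.5,
    "tumor_stage": 0.45,
    "cell_of_origin": 0.2,
    "ldh_elevated": 0.9,
    "wbc_count": 0.3,
    "extranodal_sites": 0.4,
    "ipi_high": 0.8,
    "double_expression": 0.9,
}

# White-cell count reference range used for continuous->categorical binning.
WBC_BINNING = ([4.0, 10.0], ["decreased", "normal", "increased"])


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic cohort (defaults are the
    conditions every recovery experiment runs under)."""

    n_patients: int = 160
    prevalence: float = 0.52  # R/R share of the cohort
    slide_width: int = 3584
    slide_height: int = 2560
    n_blobs: int = 3
    blob_cells: int = 10  # grid cells per tissue blob -> M ~= 30 patches
    signal_rate_pos: float = 0.3
    signal_rate_neg: float = 0.0
    nucleus_density_signal: float = 48.0  # nuclei per 512x512 patch
    nucleus_density_background: float = 12.0  # 4:1 contrast
    clinical_vars: dict = field(default_factory=lambda: dict(DEFAULT_CLINICAL_VARS))
    clinical_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_EFFECTS)
    )
    missing_rate: float = 0.05
    baseline_hazard: float = np.log(2) / 60.0  # median 60 months in non-R/R
    hazard_ratio: float = 3.0
    censor_time: float = 84.0  # months of administrative follow-up
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        for r in (self.signal_rate_pos, self.signal_rate_neg, self.missing_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")
        if self.nucleus_density_signal <= self.nucleus_density_background:
            raise ValueError("signal nucleus density must exceed background")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if min(self.slide_width, self.slide_height) < 2 * PATCH:
            raise ValueError("slide dimensions must be at least 2x patch size")


@dataclass
class CohortRecord:
    patient_id: str
    label: int  # 1 = R/R, 0 = non-relapsed & non-refractory
    slide_path: str
    clinical: dict
    survival_time: float
    event: int


@dataclass
class FeatureCohort:
    """In-memory cohort of encoded bags plus every ground truth."""

    patient_ids: list[str]
    labels: np.ndarray
    bags: list[FeatureBag]
    signal_coords: list[np.ndarray]  # per slide, (k, 2) planted-patch corners
    tissue_coords: list[np.ndarray]
    clinical: pd.DataFrame
    survival: pd.DataFrame  # columns time, event


# ---------------------------------------------------------------------------
# slides
# ---------------------------------------------------------------------------


def _grow_tissue_cells(
    gw: int, gh: int, n_blobs: int, blob_cells: int, rng: np.random.Generator
) -> set[tuple[int, int]]:
    cells: set[tuple[int, int]] = set()
    for _ in range(n_blobs):
        seed_cell = (int(rng.integers(gw)), int(rng.integers(gh)))
        blob = {seed_cell}
        frontier = [seed_cell]
        while len(blob) < blob_cells and frontier:
            cx, cy = frontier[int(rng.integers(len(frontier)))]
            nbrs = [
                (cx + dx, cy + dy)
                for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1))
                if 0 <= cx + dx < gw and 0 <= cy + dy < gh and (cx + dx, cy + dy) not in blob
            ]
            if not nbrs:
                frontier.remove((cx, cy))
                continue
            new = nbrs[int(rng.integers(len(nbrs)))]
            blob.add(new)
            frontier.append(new)
        cells |= blob
    return cells


def _draw_nuclei(
    image: np.ndarray, x0: int, y0: int, count: int, rng: np.random.Generator
) -> None:
    h, w = image.shape[:2]
    for _ in range(count):
        cx = x0 + rng.uniform(0, PATCH)
        cy = y0 + rng.uniform(0, PATCH)
        a = rng.uniform(5.0, 12.0)
        b = rng.uniform(3.0, 8.0)
        rot = rng.uniform(0, np.pi)
        rr, cc = ellipse(cy, cx, a, b, shape=(h, w), rotation=rot)
        shade = rng.integers(-12, 13, size=3)
        image[rr, cc] = np.clip(np.array([72, 46, 110]) + shade, 0, 255)


def generate_slide(
    label: int, config: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One H&E-like slide raster.

    Returns ``(image, signal_coords, tissue_coords)`` where the coordinate
    arrays hold (x, y) top-left corners of planted-signal and tissue grid
    patches. Background is near-white (saturation ~0); tissue is pink with
    saturation far above the segmentation threshold.
    """
    w, h = config.slide_width, config.slide_height
    gw, gh = w // PATCH, h // PATCH
    image = np.full((h, w, 3), 250, dtype=np.uint8)

    cells = sorted(_grow_tissue_cells(gw, gh, config.n_blobs, config.blob_cells, rng))
    rate = config.signal_rate_pos if label == 1 else config.signal_rate_neg
    signal, tissue = [], []
    for gx, gy in cells:
        x0, y0 = gx * PATCH, gy * PATCH
        tissue.append((x0, y0))
        base = np.array([226, 158, 206], dtype=np.int16)
        noise = rng.integers(-10, 11, size=(PATCH, PATCH, 3), dtype=np.int16)
        image[y0 : y0 + PATCH, x0 : x0 + PATCH] = np.clip(base + noise, 0, 255).astype(
            np.uint8
        )
        is_signal = rng.random() < rate
        density = (
            config.nucleus_density_signal if is_signal else config.nucleus_density_background
        )
        _draw_nuclei(image, x0, y0, int(rng.poisson(density)), rng)
        if is_signal:
            signal.append((x0, y0))
    to_arr = lambda lst: (
        np.array(lst, dtype=np.int64) if lst else np.empty((0, 2), dtype=np.int64)
    )
    return image, to_arr(signal), to_arr(tissue)


# ---------------------------------------------------------------------------
# clinical covariates
# ---------------------------------------------------------------------------


def generate_clinical(
    labels: np.ndarray, config: SyntheticConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Covariates whose association with the R/R label follows the stated
    log-odds effects.

    Binary variables are drawn so that the group odds ratio equals
    exp(effect); multicategory levels are exponentially tilted by level
    index; continuous variables get a mean shift of effect x SD in the R/R
    group (the equal-variance Gaussian realisation of a logistic model).
    Outcome-like variables (treatment response etc.) are never generated.
    Each cell is then masked missing independently at ``missing_rate``.
    """
    missing_vars = set(config.clinical_vars) - set(config.clinical_effects)
    if missing_vars:
        raise ValueError(f"clinical_effects missing for variables: {sorted(missing_vars)}")
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    cols: dict[str, pd.Series] = {}
    for name, var in config.clinical_vars.items():
        beta = float(config.clinical_effects[name])
        if var["kind"] == "binary":
            p0 = float(var["p0"])
            odds1 = p0 / (1 - p0) * np.exp(beta)
            p1 = odds1 / (1 + odds1)
            p = np.where(labels == 1, p1, p0)
            draws = (rng.random(n) < p).astype(int)
            col = pd.Series(np.asarray(var["levels"], dtype=object)[draws])
        elif var["kind"] == "multicategory":
            q0 = np.asarray(var["p0"], dtype=float)
            q0 = q0 / q0.sum()
            tilt = q0 * np.exp(beta * np.arange(len(q0)))
            q1 = tilt / tilt.sum()
            out = np.empty(n, dtype=object)
            levels = np.asarray(var["levels"], dtype=object)
            for lab, q in ((0, q0), (1, q1)):
                idx = np.where(labels == lab)[0]
                out[idx] = levels[rng.choice(len(q0), size=len(idx), p=q)]
            col = pd.Series(out)
        elif var["kind"] == "continuous":
            mu, sd = float(var["mean"]), float(var["sd"])
            col = pd.Series(rng.normal(mu + beta * sd * labels, sd))
        else:
            raise ValueError(f"unknown variable kind {var['kind']!r}")
        if config.missing_rate > 0:
            col = col.mask(rng.random(n) < config.missing_rate)
        cols[name] = col
    return pd.DataFrame(cols)


def default_clinical_schema(config: SyntheticConfig) -> dict[str, VariableSchema]:
    """Schema matching :func:`generate_clinical` output, with the
    white-cell count carrying a reference-range binning rule."""
    schema: dict[str, VariableSchema] = {}
    for name, var in config.clinical_vars.items():
        if var["kind"] == "continuous":
            binning = WBC_BINNING if name == "wbc_count" else None
            schema[name] = VariableSchema(kind="continuous", binning=binning)
        else:
            schema[name] = VariableSchema(kind=var["kind"], levels=list(var["levels"]))
    return schema


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


def generate_survival(
    labels: np.ndarray, config: SyntheticConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Exponential event times with hazard h0 * hazard_ratio^label and
    administrative censoring at ``censor_time``."""
    labels = np.asarray(labels, dtype=int)
    hazard = config.baseline_hazard * config.hazard_ratio**labels
    t_event = rng.exponential(1.0 / hazard)
    time = np.minimum(t_event, config.censor_time)
    event = (t_event <= config.censor_time).astype(int)
    time = np.maximum(time, 1e-6)  # survival times are strictly positive
    return pd.DataFrame({"time": time, "event": event})


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


def _cohort_labels(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    n1 = int(round(config.n_patients * config.prevalence))
    labels = np.zeros(config.n_patients, dtype=int)
    labels[:n1] = 1
    return labels[rng.permutation(config.n_patients)]


def generate_cohort(
    config: SyntheticConfig, out_dir: str | Path
) -> list[CohortRecord]:
    """Write a full cohort to disk: slide PNGs, per-slide ground-truth
    signal-patch JSON, and a manifest CSV (missing cells empty)."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        (out / "slides").mkdir(exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc

    ss = np.random.SeedSequence(config.seed)
    rng_labels, rng_clin, rng_surv, *slide_seeds = [
        np.random.default_rng(s) for s in ss.spawn(3 + config.n_patients)
    ]
    labels = _cohort_labels(config, rng_labels)
    clinical = generate_clinical(labels, config, rng_clin)
    survival = generate_survival(labels, config, rng_surv)

    records = []
    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        image, signal, tissue = generate_slide(int(labels[i]), config, slide_seeds[i])
        slide_path = out / "slides" / f"{pid}.png"
        Image.fromarray(image).save(slide_path, compress_level=1)
        with open(out / "slides" / f"{pid}_signal.json", "w") as f:
            json.dump(
                {"signal": signal.tolist(), "tissue": tissue.tolist()}, f
            )
        records.append(
            CohortRecord(
                patient_id=pid,
                label=int(labels[i]),
                slide_path=str(slide_path),
                clinical=clinical.iloc[i].to_dict(),
                survival_time=float(survival["time"].iloc[i]),
                event=int(survival["event"].iloc[i]),
            )
        )

    manifest = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "label": labels,
            "slide_path": [r.slide_path for r in records],
            "survival_time": survival["time"].to_numpy(),
            "event": survival["event"].to_numpy(),
        }
    )
    manifest = pd.concat([manifest, clinical], axis=1)
    manifest.to_csv(out / "manifest.csv", index=False, na_rep="")
    return records


def build_feature_cohort(
    config: SyntheticConfig,
    encoder: EncoderSpec | None = None,
    min_tissue_fraction: float = 0.25,
) -> FeatureCohort:
    """Generate, segment and encode a cohort slide-by-slide in memory.

    Streaming keeps only one slide raster alive at a time; the returned
    cohort holds encoded bags, ground-truth planted-patch coordinates, the
    clinical table and survival outcomes.
    """
    encoder = encoder or EncoderSpec(kind="fixture", seed=config.seed)
    ss = np.random.SeedSequence(config.seed)
    rng_labels, rng_clin, rng_surv, *slide_seeds = [
        np.random.default_rng(s) for s in ss.spawn(3 + config.n_patients)
    ]
    labels = _cohort_labels(config, rng_labels)
    clinical = generate_clinical(labels, config, rng_clin)
    survival = generate_survival(labels, config, rng_surv)

    ids, bags, sig, tis = [], [], [], []
    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        image, signal, tissue = generate_slide(int(labels[i]), config, slide_seeds[i])
        mask = compute_tissue_mask(image)
        grid = extract_patch_grid(
            mask,
            config.slide_width,
            config.slide_height,
            min_tissue_fraction=min_tissue_fraction,
            slide_id=pid,
        )
        bags.append(encode_slide(image, grid, encoder))
        ids.append(pid)
        sig.append(signal)
        tis.append(tissue)
    clinical.index = ids
    survival.index = ids
    return FeatureCohort(
        patient_ids=ids,
        labels=labels,
        bags=bags,
        signal_coords=sig,
        tissue_coords=tis,
        clinical=clinical,
        survival=survival,
    )
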