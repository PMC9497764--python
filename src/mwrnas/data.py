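"""MWR tabular data: loading, class balancing, splitting, and synthesis.

A patient record is 44 temperatures (°C): for each mammary gland, points
0–8 around and on the nipple plus an axillary point (9), each measured on
the skin and at 3–5 cm depth (40 readings), plus reference points T1/T2
under the chest, also at skin and depth (4 readings). The label is binary:
0 = low risk, 1 = high risk of breast cancer.

The synthetic generator emulates the structure that makes the task
learnable from thermometry: low-risk patients have near-symmetric bilateral
temperature fields (left and right glands share a common per-point thermal
pattern, differing only by a small asymmetry term), while high-risk
patients carry a localized hotspot — a contiguous run of depth points on
one gland elevated by ``hotspot_delta``, with half that elevation showing
through on the corresponding skin points. Skin readings partially track
the deep pattern (coupling 0.5), reflecting thermal conduction toward the
surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MwrDataset",
    "SyntheticConfig",
    "DataSplit",
    "default_columns",
    "load_mwr_table",
    "save_mwr_table",
    "balance_classes",
    "split",
    "generate_synthetic",
    "standardize",
    "SchemaError",
]

logger = logging.getLogger(__name__)

N_FEATURES = 44
GLAND_POINTS = 10  # points 0-8 around/on nipple + axillary point 9
SKIN_DEPTH_COUPLING = 0.5

LABEL_COLUMN = "label"
_LABEL_MAP = {"low": 0, "high": 1, "0": 0, "1": 1, 0: 0, 1: 1, 0.0: 0, 1.0: 1}


class SchemaError(ValueError):
    """Raised when required columns are missing from an input table."""


def default_columns() -> list[str]:
    """Canonical 44-column schema: depth then skin, left gland, right gland,
    references T1/T2."""
    cols = []
    for layer in ("depth", "skin"):
        for side in ("L", "R"):
            cols.extend(f"{side}{i}_{layer}" for i in range(GLAND_POINTS))
        cols.extend(f"{ref}_{layer}" for ref in ("T1", "T2"))
    return cols


def depth_indices(side: str) -> list[int]:
    """Column indices of the depth readings for gland side 'L' or 'R'."""
    cols = default_columns()
    return [cols.index(f"{side}{i}_depth") for i in range(GLAND_POINTS)]


def skin_indices(side: str) -> list[int]:
    cols = default_columns()
    return [cols.index(f"{side}{i}_skin") for i in range(GLAND_POINTS)]


@dataclass
class MwrDataset:
    features: np.ndarray  # (n_patients, 44), °C
    labels: np.ndarray  # (n_patients,), {0, 1}
    column_names: list[str] = field(default_factory=default_columns)
    provenance: str = "real"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2 or self.features.shape[1] != N_FEATURES:
            raise ValueError(f"features must be (n, {N_FEATURES})")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels disagree on patient count")
        if np.isnan(self.features).any():
            raise ValueError("missing values in features")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 (low risk) or 1 (high risk)")

    def __len__(self) -> int:
        return self.features.shape[0]

    @property
    def class_counts(self) -> tuple[int, int]:
        return int(np.sum(self.labels == 0)), int(np.sum(self.labels == 1))

    def subset(self, idx) -> "MwrDataset":
        return MwrDataset(
            self.features[idx], self.labels[idx], list(self.column_names), self.provenance
        )

    def as_xy(self) -> tuple[np.ndarray, np.ndarray]:
        return self.features, self.labels


def load_mwr_table(
    path,
    column_map: dict[str, str] | None = None,
    label_column: str = LABEL_COLUMN,
) -> MwrDataset:
    """Read a delimited-text MWR table.

    ``column_map`` maps canonical names (``default_columns()``) to the
    file's actual headers for files that use a different nomenclature.
    Rows with any missing or unparseable value are dropped with a logged
    count. Labels are mapped to {0, 1} ('low'/'high' accepted).
    """
    df = pd.read_csv(path)
    column_map = column_map or {}
    wanted = [(c, column_map.get(c, c)) for c in default_columns()]
    missing = [src for _, src in wanted if src not in df.columns]
    label_src = column_map.get(label_column, label_column)
    if label_src not in df.columns:
        missing.append(label_src)
    if missing:
        raise SchemaError(f"missing required columns: {missing}")

    feats = df[[src for _, src in wanted]].apply(pd.to_numeric, errors="coerce")
    labels = df[label_src].map(
        lambda v: _LABEL_MAP.get(v, _LABEL_MAP.get(str(v).strip().lower()))
    )
    keep = feats.notna().all(axis=1) & labels.notna()
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d rows with missing/unparseable values", dropped)
    return MwrDataset(
        features=feats[keep].to_numpy(),
        labels=labels[keep].to_numpy(dtype=int),
        column_names=default_columns(),
        provenance="real",
    )


def save_mwr_table(dataset: MwrDataset, path) -> None:
    df = pd.DataFrame(dataset.features, columns=dataset.column_names)
    df[LABEL_COLUMN] = dataset.labels
    df.to_csv(path, index=False)


def balance_classes(
    dataset: MwrDataset, rng: np.random.Generator, method: str = "undersample"
) -> MwrDataset:
    """Equalize class counts; default random undersampling of the majority
    class without replacement (keeps only real measurements). Oversampling
    of the minority (with replacement) is available behind the flag."""
    n0, n1 = dataset.class_counts
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    idx0 = np.flatnonzero(dataset.labels == 0)
    idx1 = np.flatnonzero(dataset.labels == 1)
    if method == "undersample":
        target = min(n0, n1)
        idx0 = rng.choice(idx0, size=target, replace=False)
        idx1 = rng.choice(idx1, size=target, replace=False)
    elif method == "oversample":
        target = max(n0, n1)
        if n0 < target:
            idx0 = rng.choice(idx0, size=target, replace=True)
        if n1 < target:
            idx1 = rng.choice(idx1, size=target, replace=True)
    else:
        raise ValueError(f"unknown balancing method: {method!r}")
    idx = np.concatenate([idx0, idx1])
    rng.shuffle(idx)
    return dataset.subset(idx)


@dataclass
class DataSplit:
    train: MwrDataset
    validation: MwrDataset
    test: MwrDataset


def split(
    dataset: MwrDataset,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    rng: np.random.Generator | None = None,
) -> DataSplit:
    """Stratified train/validation/test split (default 60/20/20).

    Within each class, indices are shuffled and cut at the cumulative
    fraction boundaries, so subset sizes are within ±1 of the exact
    fractions per class, disjoint, and exhaustive.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = rng if rng is not None else np.random.default_rng(0)
    parts: list[list[np.ndarray]] = [[], [], []]
    for cls in (0, 1):
        idx = np.flatnonzero(dataset.labels == cls)
        if idx.size < 3:
            raise ValueError(f"class {cls} has fewer than 3 members; cannot stratify")
        rng.shuffle(idx)
        c1 = int(np.floor(fractions[0] * idx.size))
        c2 = int(np.floor((fractions[0] + fractions[1]) * idx.size))
        parts[0].append(idx[:c1])
        parts[1].append(idx[c1:c2])
        parts[2].append(idx[c2:])
    subsets = []
    for p in parts:
        idx = np.concatenate(p)
        rng.shuffle(idx)
        subsets.append(dataset.subset(idx))
    return DataSplit(*subsets)


def standardize(
    train: MwrDataset, *others: MwrDataset
) -> tuple[MwrDataset, ...]:
    """Z-score features column-wise with mean/sd fit on the training set.

    Absolute temperatures sit near 33-36 °C, so without centering any
    nonzero shared weight saturates the output sigmoid and every topology
    scores identically; standardization (training statistics only, applied
    to all subsets) is what makes shared-weight evaluation informative.
    """
    mu = train.features.mean(axis=0)
    sd = train.features.std(axis=0)
    sd[sd == 0] = 1.0

    def z(ds: MwrDataset) -> MwrDataset:
        return MwrDataset(
            (ds.features - mu) / sd, ds.labels, list(ds.column_names), ds.provenance
        )

    return tuple(z(ds) for ds in (train, *others))


@dataclass
class SyntheticConfig:
    """Generator parameters; temperatures in °C.

    ``noise_sd`` is the total per-reading standard deviation; of that,
    bilateral coupling means most of the variation is a per-point thermal
    pattern shared by the two glands, and only ``asymmetry_sd`` (the
    standard deviation of the left-right difference) is side-specific.
    """

    n_low: int = 200
    n_high: int = 200
    skin_baseline: float = 33.5
    depth_baseline: float = 36.5
    noise_sd: float = 0.4
    hotspot_delta: float = 1.5
    hotspot_points: int = 3
    asymmetry_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_low + self.n_high < 10:
            raise ValueError("need at least 10 patients")
        if min(self.noise_sd, self.asymmetry_sd) < 0 or self.hotspot_points < 1:
            raise ValueError("noise/asymmetry sds must be >= 0, hotspot_points >= 1")
        if self.asymmetry_sd > self.noise_sd * np.sqrt(2):
            raise ValueError("asymmetry_sd cannot exceed noise_sd * sqrt(2)")


def generate_synthetic(config: SyntheticConfig) -> MwrDataset:
    """Draw a synthetic MWR cohort.

    Per patient and gland point, a common bilateral thermal deviation is
    drawn and shared by the left and right readings; each side adds an
    independent deviation of sd ``asymmetry_sd / sqrt(2)`` so the
    left-right difference has sd ``asymmetry_sd`` and every reading has
    total sd ``noise_sd``. Skin readings couple to the same deep pattern
    with factor 0.5 plus their own surface variation. High-risk patients
    add ``hotspot_delta`` to ``hotspot_points`` contiguous depth points on
    one uniformly chosen gland and half that on the matching skin points.
    Reference points T1/T2 are baseline + independent noise.
    """
    rng = np.random.default_rng(config.seed)
    cols = default_columns()
    n = config.n_low + config.n_high
    side_sd = config.asymmetry_sd / np.sqrt(2.0)
    common_sd = float(np.sqrt(max(config.noise_sd**2 - side_sd**2, 0.0)))
    # skin's own variation on top of the coupled deep pattern, keeping the
    # per-reading sd at noise_sd
    skin_own_var = max(
        config.noise_sd**2 - (SKIN_DEPTH_COUPLING * common_sd) ** 2 - side_sd**2, 0.0
    )
    skin_own_sd = float(np.sqrt(skin_own_var))

    X = np.empty((n, N_FEATURES))
    labels = np.zeros(n, dtype=int)
    labels[config.n_low :] = 1
    col_idx = {c: k for k, c in enumerate(cols)}

    for row in range(n):
        common = rng.normal(0.0, common_sd, size=GLAND_POINTS)
        for side in ("L", "R"):
            side_dev = rng.normal(0.0, side_sd, size=GLAND_POINTS)
            depth = config.depth_baseline + common + side_dev
            skin = (
                config.skin_baseline
                + SKIN_DEPTH_COUPLING * common
                + rng.normal(0.0, skin_own_sd, size=GLAND_POINTS)
                + rng.normal(0.0, side_sd, size=GLAND_POINTS)
            )
            for i in range(GLAND_POINTS):
                X[row, col_idx[f"{side}{i}_depth"]] = depth[i]
                X[row, col_idx[f"{side}{i}_skin"]] = skin[i]
        for ref in ("T1", "T2"):
            X[row, col_idx[f"{ref}_depth"]] = config.depth_baseline + rng.normal(
                0.0, config.noise_sd
            )
            X[row, col_idx[f"{ref}_skin"]] = config.skin_baseline + rng.normal(
                0.0, config.noise_sd
            )
        if labels[row] == 1:
            side = "L" if rng.random() < 0.5 else "R"
            width = min(config.hotspot_points, GLAND_POINTS)
            start = int(rng.integers(0, GLAND_POINTS - width + 1))
            for i in range(start, start + width):
                X[row, col_idx[f"{side}{i}_depth"]] += config.hotspot_delta
                X[row, col_idx[f"{side}{i}_skin"]] += config.hotspot_delta / 2.0

    return MwrDataset(X, labels, cols, provenance="synthetic")
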