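"""Nearest-centroid diabetes-subtype classification.

Newly diagnosed individuals are assigned to one of five subtypes: GADA
positivity gates assignment to SAID (severe autoimmune diabetes); everyone
else is assigned to SIDD, SIRD, MOD or MARD by the nearest centroid in a
z-scored feature space (Euclidean distance), using standardisation constants
and centroids frozen from a training cohort.

Three glycemia variants are supported, differing only in the feature list:

- ``hba1c``:         age at onset, BMI, glycated haemoglobin (%), HOMA-B, HOMA-IR
- ``fpg``:           age at onset, BMI, fasting plasma glucose (mg/dL), HOMA-B, HOMA-IR
- ``glycemia_free``: age at onset, BMI, HOMA-B, HOMA-IR

The ``fpg`` variant replaces glycated haemoglobin with fasting glucose so
cohorts without HbA1c measurements can be classified; ``glycemia_free``
drops the glycemia feature altogether, which quantifies how much glycemia
contributes to variant disagreement.  :func:`concordance` computes the
percent agreement between any two variants' label vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.cluster import KMeans

from ._errors import ContractError, FittingError, SchemaError
from .simulate import SUBTYPES

VARIANT_FEATURES: dict[str, tuple[str, ...]] = {
    "hba1c": ("age_at_onset", "bmi", "hba1c", "homa_b", "homa_ir"),
    "fpg": ("age_at_onset", "bmi", "fpg", "homa_b", "homa_ir"),
    "glycemia_free": ("age_at_onset", "bmi", "homa_b", "homa_ir"),
}

#: Fixed tie-break order for exact distance ties (deterministic by design).
TIE_BREAK_ORDER = ("SIDD", "SIRD", "MOD", "MARD")


@dataclass
class SubtypeCentroids:
    """Frozen standardisation constants plus per-subtype centroid vectors.

    ``means``/``sds`` are per-feature training statistics; ``centroids`` maps
    each subtype to its centre in *standardised* space.
    """

    variant: str
    feature_names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    centroids: dict[str, np.ndarray]
    provenance: str = "fitted_by_kmeans"

    def __post_init__(self):
        self.feature_names = tuple(self.feature_names)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.centroids = {k: np.asarray(v, dtype=float) for k, v in self.centroids.items()}
        if self.variant not in VARIANT_FEATURES:
            raise SchemaError(f"unknown variant {self.variant!r}")
        expected = VARIANT_FEATURES[self.variant]
        if self.feature_names != expected:
            raise SchemaError(
                f"variant {self.variant!r} requires features {expected}, got {self.feature_names}"
            )
        p = len(self.feature_names)
        if self.means.shape != (p,) or self.sds.shape != (p,):
            raise SchemaError("means/sds length must match feature count")
        if np.any(self.sds <= 0):
            raise SchemaError("all standardisation SDs must be > 0")
        if set(self.centroids) != set(SUBTYPES):
            raise SchemaError(f"centroids must be exactly {SUBTYPES}, got {sorted(self.centroids)}")
        for name, c in self.centroids.items():
            if c.shape != (p,):
                raise SchemaError(f"centroid {name!r} has length {c.shape}, expected {p}")


@dataclass(frozen=True)
class ClassificationResult:
    """Assigned subtype for one participant.

    ``distances`` is empty for SAID (the GADA gate bypasses the centroid
    comparison); otherwise it holds the Euclidean distance to each of the
    four centroids in standardised space.
    """

    participant_id: str
    subtype: str
    distances: dict[str, float] = field(default_factory=dict)
    classification_exam: int | None = None
    diagnosis_to_exam_years: float | None = None


def standardize(x, means, sds, feature_names=None, expected_names=None):
    """Elementwise z-score ``(x - mean) / sd``.

    When both name lists are given they must match exactly (same order);
    a :class:`ContractError` lists any missing features.
    """
    if feature_names is not None and expected_names is not None:
        missing = [f for f in expected_names if f not in feature_names]
        if missing:
            raise ContractError(f"missing feature(s): {', '.join(missing)}")
        if tuple(feature_names) != tuple(expected_names):
            raise ContractError(
                f"feature order mismatch: got {tuple(feature_names)}, expected {tuple(expected_names)}"
            )
    x = np.asarray(x, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if np.any(sds <= 0):
        raise ContractError("standardisation SDs must be > 0")
    return (x - np.asarray(means, dtype=float)) / sds


def destandardize(z, means, sds):
    """Inverse of :func:`standardize`."""
    return np.asarray(z, dtype=float) * np.asarray(sds, dtype=float) + np.asarray(means, dtype=float)


def fit_centroids(
    training: pd.DataFrame,
    variant: str = "fpg",
    k_means_restarts: int = 10,
    seed: int = 0,
) -> SubtypeCentroids:
    """Fit k-means (k=4) centroids on a GADA-negative training cohort.

    ``training`` needs one column per variant feature.  Clusters are mapped
    to subtype names by their centres in standardised space: lowest HOMA-B
    -> SIDD; highest HOMA-IR among the rest -> SIRD; highest BMI among the
    rest -> MOD; the remainder -> MARD.  This mirrors the clinical subtype
    definitions (beta-cell failure, insulin resistance, obesity, and mild
    age-related disease respectively).
    """
    if variant not in VARIANT_FEATURES:
        raise SchemaError(f"unknown variant {variant!r}")
    feats = VARIANT_FEATURES[variant]
    missing = [f for f in feats if f not in training.columns]
    if missing:
        raise ContractError(f"training data missing feature(s): {', '.join(missing)}")
    X = training.loc[:, list(feats)].to_numpy(dtype=float)
    if len(X) < 4:
        raise FittingError(f"need at least 4 training individuals, got {len(X)}")
    if np.isnan(X).any():
        raise FittingError("training data contains missing feature values")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = [f for f, s in zip(feats, sds) if s <= 0]
    if zero:
        raise FittingError(f"zero-variance feature(s): {', '.join(zero)}")
    Z = (X - means) / sds
    km = KMeans(n_clusters=4, n_init=k_means_restarts, random_state=seed).fit(Z)
    centers = km.cluster_centers_

    remaining = list(range(4))
    labelled: dict[str, np.ndarray] = {}
    order = [("SIDD", feats.index("homa_b"), "min"),
             ("SIRD", feats.index("homa_ir"), "max"),
             ("MOD", feats.index("bmi"), "max")]
    for name, col, how in order:
        vals = centers[remaining, col]
        pick = remaining[int(np.argmin(vals) if how == "min" else np.argmax(vals))]
        labelled[name] = centers[pick]
        remaining.remove(pick)
    labelled["MARD"] = centers[remaining[0]]
    return SubtypeCentroids(
        variant=variant,
        feature_names=feats,
        means=means,
        sds=sds,
        centroids=labelled,
        provenance="fitted_by_kmeans",
    )


def save_centroids(centroids: SubtypeCentroids, path: str | Path) -> Path:
    """Serialise a centroid set to YAML."""
    path = Path(path)
    payload = {
        "variant": centroids.variant,
        "feature_names": list(centroids.feature_names),
        "means": [float(v) for v in centroids.means],
        "sds": [float(v) for v in centroids.sds],
        "centroids": {k: [float(x) for x in v] for k, v in centroids.centroids.items()},
        "provenance": centroids.provenance,
    }
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def load_centroids(path: str | Path) -> SubtypeCentroids:
    """Load a centroid set from YAML, validating the schema.

    Published centroid sets (e.g. from the original clustering cohort) can be
    supplied this way; nothing is bundled.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: expected a mapping")
    required = {"variant", "feature_names", "means", "sds", "centroids"}
    missing = required - set(raw)
    if missing:
        raise SchemaError(f"{path}: missing key(s): {', '.join(sorted(missing))}")
    try:
        return SubtypeCentroids(
            variant=raw["variant"],
            feature_names=tuple(raw["feature_names"]),
            means=raw["means"],
            sds=raw["sds"],
            centroids=raw["centroids"],
            provenance=raw.get("provenance", "loaded_from_file"),
        )
    except SchemaError:
        raise
    except (TypeError, ValueError, KeyError) as exc:
        raise SchemaError(f"{path}: invalid centroid file: {exc}") from exc


def assign_subtype(
    features: dict[str, float],
    centroids: SubtypeCentroids,
    gada_positive: bool = False,
    participant_id: str = "",
    classification_exam: int | None = None,
    diagnosis_to_exam_years: float | None = None,
) -> ClassificationResult:
    """Assign one individual to a subtype.

    GADA-positive individuals are assigned to SAID outright.  Otherwise the
    feature vector is standardised with the frozen training constants and
    assigned to the subtype with the nearest centroid; exact distance ties
    break in the fixed order SIDD < SIRD < MOD < MARD.
    """
    if gada_positive:
        return ClassificationResult(
            participant_id=participant_id,
            subtype="SAID",
            distances={},
            classification_exam=classification_exam,
            diagnosis_to_exam_years=diagnosis_to_exam_years,
        )
    missing = [f for f in centroids.feature_names if f not in features or pd.isna(features[f])]
    if missing:
        raise ContractError(f"missing classification feature(s): {', '.join(missing)}")
    x = np.array([features[f] for f in centroids.feature_names], dtype=float)
    z = standardize(x, centroids.means, centroids.sds)
    distances = {
        s: float(np.linalg.norm(z - centroids.centroids[s])) for s in TIE_BREAK_ORDER
    }
    best = min(distances.values())
    subtype = next(s for s in TIE_BREAK_ORDER if distances[s] == best)
    return ClassificationResult(
        participant_id=participant_id,
        subtype=subtype,
        distances=distances,
        classification_exam=classification_exam,
        diagnosis_to_exam_years=diagnosis_to_exam_years,
    )


def classify_cohort(features: pd.DataFrame, centroids: SubtypeCentroids) -> pd.DataFrame:
    """Vectorised convenience wrapper over :func:`assign_subtype`.

    ``features`` needs the variant's feature columns plus ``participant_id``,
    ``gada_positive``, and optionally ``classification_exam`` /
    ``diagnosis_to_exam_years``; returns one row per participant with the
    assigned ``subtype`` and a ``dist_<subtype>`` column per centroid.
    """
    rows = []
    for _, r in features.iterrows():
        res = assign_subtype(
            {f: r[f] for f in centroids.feature_names if f in features.columns},
            centroids,
            gada_positive=bool(r.get("gada_positive", False)),
            participant_id=str(r["participant_id"]),
            classification_exam=r.get("classification_exam"),
            diagnosis_to_exam_years=r.get("diagnosis_to_exam_years"),
        )
        row = {
            "participant_id": res.participant_id,
            "subtype": res.subtype,
            "classification_exam": res.classification_exam,
            "diagnosis_to_exam_years": res.diagnosis_to_exam_years,
        }
        for s in TIE_BREAK_ORDER:
            row[f"dist_{s}"] = res.distances.get(s, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def separated_feature_cohort(
    n_per_subtype: int = 25,
    separation: float = 6.0,
    noise_sd: float = 1.0,
    variant: str = "fpg",
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic classification features forming four well-separated blobs.

    Each subtype's blob is offset from a common physiological baseline along
    its defining feature (low HOMA-B for SIDD, high HOMA-IR for SIRD, high
    BMI for MOD; MARD sits at the baseline) by ``separation * noise_sd``,
    so the minimum between-blob distance is ``separation`` within-cluster
    SDs.  Returns a feature table with ``participant_id``, ``gada_positive``
    and a ``true_subtype`` column for accuracy evaluation.
    """
    if variant not in VARIANT_FEATURES:
        raise SchemaError(f"unknown variant {variant!r}")
    feats = VARIANT_FEATURES[variant]
    base = {"age_at_onset": 50.0, "bmi": 30.0, "hba1c": 7.0, "fpg": 120.0,
            "homa_b": 100.0, "homa_ir": 15.0}
    a = separation * max(noise_sd, 1.0)
    # every feature varies across subtypes (younger onset in MOD, older in
    # MARD, higher glycemia in SIDD), so noise-free cohorts still have
    # positive variance on every axis
    offsets = {
        "SIDD": {"homa_b": -a, "fpg": +0.5 * a, "hba1c": +0.5 * a},
        "SIRD": {"homa_ir": +a},
        "MOD": {"bmi": +a, "age_at_onset": -0.5 * a},
        "MARD": {"age_at_onset": +0.5 * a},
    }
    rng = np.random.default_rng(seed)
    rows = []
    for subtype in TIE_BREAK_ORDER:
        centre = np.array([base[f] + offsets[subtype].get(f, 0.0) for f in feats])
        X = centre + rng.normal(0.0, noise_sd, (n_per_subtype, len(feats)))
        X = np.maximum(X, 0.1)  # features must stay positive
        for i in range(n_per_subtype):
            row = {"participant_id": f"{subtype}-{i:04d}", "gada_positive": False,
                   "true_subtype": subtype}
            row.update(dict(zip(feats, X[i])))
            rows.append(row)
    return pd.DataFrame(rows)


def concordance(labels_a, labels_b) -> tuple[float, pd.DataFrame]:
    """Percent agreement between two aligned label vectors.

    Returns ``(percent, confusion)`` where ``percent`` is
    ``100 * #identical / n`` rounded to one decimal and ``confusion`` is the
    cross-tabulation of the two labelings.
    """
    a = pd.Series(list(labels_a))
    b = pd.Series(list(labels_b))
    if len(a) != len(b):
        raise ContractError(f"label lists differ in length: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ContractError("cannot compute concordance on empty label lists")
    pct = round(100.0 * float((a.to_numpy() == b.to_numpy()).sum()) / len(a), 1)
    confusion = pd.crosstab(a, b, rownames=["a"], colnames=["b"])
    return pct, confusion
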