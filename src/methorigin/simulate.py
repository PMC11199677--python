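"""Synthetic multi-class methylation and expression cohorts.

The generators emulate the statistical structure the pipeline assumes of
a pan-cancer cohort: per-feature background levels shared across classes,
a disjoint set of planted tissue-specific markers per class whose
class-conditional mean is shifted, inter-sample noise, and (for
methylation) missing values.

Methylation beta values are simulated as logit-normals: a per-feature
background mean is drawn from a bimodal (hypo/hyper) distribution with
modes near 0.2 and 0.8 — the canonical genome-wide 450K beta shape —
sample noise is added on the logit scale, and the result is mapped back
through the logistic function and clipped to [1e-6, 1-1e-6]. Marker
shifts of +/- delta are applied to the class-conditional mean on the
beta scale before the noise, so the planted effect size is interpretable
in beta units. Expression values are log-normal with log2 fold-change
shifts and no missing entries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .containers import LabelledDataset, OmicsMatrix, SyntheticTruth

_CLIP = 1e-6

#: desk-scale default cohort: 6 classes x 100 samples, 5,000 CpGs,
#: 50 planted markers per class, effect size 0.3 beta units
DEFAULT_METHYLATION = dict(
    n_classes=6, n_per_class=100, n_features=5000,
    n_markers_per_class=50, delta=0.3, sd_logit=0.5, missing_rate=0.0,
)

#: the 20-class cohort shape of the published study (20 types, ~337/type)
FULL_COHORT = dict(
    n_classes=20, n_per_class=337, n_features=5000,
    n_markers_per_class=50, delta=0.3, sd_logit=0.5, missing_rate=0.0,
)


def _ids(prefix: str, n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _class_labels(n_classes: int) -> list[str]:
    return [f"C{i:02d}" for i in range(1, n_classes + 1)]


def _plant_markers(rng, feature_ids, n_classes, n_markers_per_class, classes):
    chosen = rng.choice(len(feature_ids), size=n_classes * n_markers_per_class, replace=False)
    markers = {}
    for c, cls in enumerate(classes):
        block = chosen[c * n_markers_per_class:(c + 1) * n_markers_per_class]
        markers[cls] = [feature_ids[j] for j in sorted(block)]
    return markers


def generate_methylation(
    n_classes: int = DEFAULT_METHYLATION["n_classes"],
    n_per_class: int = DEFAULT_METHYLATION["n_per_class"],
    n_features: int = DEFAULT_METHYLATION["n_features"],
    n_markers_per_class: int = DEFAULT_METHYLATION["n_markers_per_class"],
    delta: float = DEFAULT_METHYLATION["delta"],
    sd_logit: float = DEFAULT_METHYLATION["sd_logit"],
    missing_rate: float = DEFAULT_METHYLATION["missing_rate"],
    seed: int = 0,
) -> LabelledDataset:
    """Simulate a balanced multi-class beta-value cohort with planted
    class-specific differentially methylated sites.

    Each class gets ``n_markers_per_class`` markers (disjoint across
    classes); a marker's class-conditional mean is shifted by ``delta``
    with direction (hyper vs hypo) chosen by fair coin, falling back to
    the feasible direction when the coin's choice would leave (0, 1).
    ``missing_rate`` of cells are masked uniformly at random.

    Returns a :class:`LabelledDataset` whose ``truth`` records the
    planted markers.
    """
    if n_markers_per_class * n_classes > n_features:
        raise ValueError("n_markers_per_class * n_classes exceeds n_features")
    if not 0 <= delta < 1:
        raise ValueError(f"delta must lie in [0,1), got {delta}")
    if not 0 <= missing_rate <= 1:
        raise ValueError(f"missing_rate must lie in [0,1], got {missing_rate}")
    rng = np.random.default_rng(seed)
    feature_ids = _ids("cg", n_features)
    classes = _class_labels(n_classes)
    sample_ids = [f"S_{cls}_{i:04d}" for cls in classes for i in range(1, n_per_class + 1)]
    y = np.repeat(np.arange(n_classes), n_per_class)

    # bimodal background: hypo/hyper modes near 0.2 / 0.8, 50/50 mixture,
    # jittered on the logit scale
    mode = rng.random(n_features) < 0.5
    base = np.where(mode, 0.2, 0.8)
    mu = expit(logit(base) + rng.normal(0.0, 0.3, size=n_features))

    # class-conditional means: background everywhere, +/- delta at markers
    markers = _plant_markers(rng, feature_ids, n_classes, n_markers_per_class, classes)
    fid_index = {f: j for j, f in enumerate(feature_ids)}
    class_mean = np.tile(mu[:, None], (1, n_classes))
    for c, cls in enumerate(classes):
        for f in markers[cls]:
            j = fid_index[f]
            direction = 1.0 if rng.random() < 0.5 else -1.0
            shifted = mu[j] + direction * delta
            if not 0.0 < shifted < 1.0:
                shifted = mu[j] - direction * delta
            if not 0.0 < shifted < 1.0:
                raise ValueError(
                    f"delta={delta} pushes marker {f} (background mean {mu[j]:.3f}) outside (0,1)"
                )
            class_mean[j, c] = shifted

    noise = rng.normal(0.0, sd_logit, size=(n_features, len(sample_ids)))
    values = expit(logit(class_mean[:, y]) + noise)
    np.clip(values, _CLIP, 1.0 - _CLIP, out=values)

    if missing_rate > 0:
        mask = rng.random(values.shape) < missing_rate
        values[mask] = np.nan

    frame = pd.DataFrame(values, index=pd.Index(feature_ids, name="feature"), columns=sample_ids)
    labels = pd.Series([classes[c] for c in y], index=sample_ids, name="label")
    truth = SyntheticTruth(
        markers=markers,
        effect_size=delta,
        baseline_means={f: float(m) for f, m in zip(feature_ids, mu)},
        missing_rate=missing_rate,
    )
    return LabelledDataset(OmicsMatrix(frame, domain="beta"), labels, truth=truth)


def generate_expression(
    n_classes: int = 6,
    n_per_class: int = 100,
    n_features: int = 5000,
    n_markers_per_class: int = 50,
    log2fc: float = 1.0,
    dispersion: float = 1.0,
    seed: int = 0,
) -> LabelledDataset:
    """Simulate a nonnegative FPKM-like expression cohort.

    Background log2 expression per feature is Gaussian; markers are
    shifted up or down (fair coin) by ``log2fc`` in their own class.
    ``dispersion`` is the inter-sample SD on the log2 scale. Expression
    cohorts carry no missing values.
    """
    if n_markers_per_class * n_classes > n_features:
        raise ValueError("n_markers_per_class * n_classes exceeds n_features")
    if dispersion <= 0:
        raise ValueError(f"dispersion must be > 0, got {dispersion}")
    rng = np.random.default_rng(seed)
    feature_ids = _ids("g", n_features)
    classes = _class_labels(n_classes)
    sample_ids = [f"S_{cls}_{i:04d}" for cls in classes for i in range(1, n_per_class + 1)]
    y = np.repeat(np.arange(n_classes), n_per_class)

    mu = rng.normal(3.0, 2.0, size=n_features)  # log2 FPKM baseline
    markers = _plant_markers(rng, feature_ids, n_classes, n_markers_per_class, classes)
    fid_index = {f: j for j, f in enumerate(feature_ids)}
    class_mean = np.tile(mu[:, None], (1, n_classes))
    for c, cls in enumerate(classes):
        for f in markers[cls]:
            direction = 1.0 if rng.random() < 0.5 else -1.0
            class_mean[fid_index[f], c] = mu[fid_index[f]] + direction * log2fc

    log2v = class_mean[:, y] + rng.normal(0.0, dispersion, size=(n_features, len(sample_ids)))
    values = np.exp2(log2v)

    frame = pd.DataFrame(values, index=pd.Index(feature_ids, name="feature"), columns=sample_ids)
    labels = pd.Series([classes[c] for c in y], index=sample_ids, name="label")
    truth = SyntheticTruth(
        markers=markers,
        effect_size=log2fc,
        baseline_means={f: float(m) for f, m in zip(feature_ids, mu)},
        missing_rate=0.0,
    )
    return LabelledDataset(OmicsMatrix(frame, domain="expression"), labels, truth=truth)


def inject_missing(matrix: OmicsMatrix, per_feature_rates, seed: int = 0) -> OmicsMatrix:
    """Mask cells of designated features at given Bernoulli rates.

    ``per_feature_rates`` maps feature ID -> rate in [0, 1], or is a
    single rate applied to every feature. Only the mask changes: observed
    values are untouched, and the realized per-feature missing fraction
    is binomial around the requested rate.
    """
    if np.isscalar(per_feature_rates):
        rates = {f: float(per_feature_rates) for f in matrix.feature_ids}
    else:
        rates = {f: float(r) for f, r in dict(per_feature_rates).items()}
    for f, r in rates.items():
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"missing rate for {f!r} outside [0,1]: {r}")
        if f not in matrix.values.index:
            raise KeyError(f"feature {f!r} not in matrix")
    rng = np.random.default_rng(seed)
    frame = matrix.values.copy()
    n = matrix.n_samples
    for f in matrix.feature_ids:  # matrix order, for determinism
        r = rates.get(f)
        if not r:
            continue
        mask = rng.random(n) < r
        row = frame.loc[f].to_numpy(dtype=float)
        row[mask] = np.nan
        frame.loc[f] = row
    return OmicsMatrix(frame, domain=matrix.domain)


def paired_profiles(seed: int = 0, n_classes: int = 6, n_per_class: int = 100,
                    n_features: int = 2000, n_markers_per_class: int = 50,
                    delta: float = 0.3, log2fc: float = 0.25):
    """A methylation/expression pair over the same samples and labels:
    strong planted methylation signal, weak expression signal — the
    setting used to compare profiles."""
    meth = generate_methylation(
        n_classes=n_classes, n_per_class=n_per_class, n_features=n_features,
        n_markers_per_class=n_markers_per_class, delta=delta, seed=seed,
    )
    expr = generate_expression(
        n_classes=n_classes, n_per_class=n_per_class, n_features=n_features,
        n_markers_per_class=n_markers_per_class, log2fc=log2fc, seed=seed + 1,
    )
    expr.matrix.values.columns = meth.matrix.sample_ids
    expr = LabelledDataset(
        OmicsMatrix(expr.matrix.values, domain="expression"), meth.labels, truth=expr.truth
    )
    return {"methylation": meth, "expression": expr}
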