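"""Run configuration: one object holding every tunable the pipeline reads.

A single global seed lives here; each stage derives its own generator
deterministically from it (see :func:`derive_seed`), so re-running one
stage in isolation reproduces the full run's behaviour.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: the eight classifier configurations the pipeline compares
CLASSIFIER_NAMES = ("RF", "SVM", "KNN", "DT", "LDA", "LASSO", "NN", "NBC")

DEFAULT_CLASSIFIER_PARAMS: dict[str, dict] = {
    "RF": {"n_trees": 200},
    "SVM": {"C": 1.0},
    "KNN": {"k": 5},
    "DT": {},
    "LDA": {},
    "LASSO": {"C": 1.0},
    "NN": {"hidden": (128,), "max_epochs": 500},
    "NBC": {},
}


def _check_fraction(name: str, value: float, closed_low: bool = False) -> None:
    low_ok = value >= 0 if closed_low else value > 0
    if not (low_ok and value <= 1):
        lo = "[0" if closed_low else "(0"
        raise ValueError(f"{name} must lie in {lo},1], got {value}")


@dataclass
class RunConfig:
    """Pipeline-wide settings.

    Defaults encode the published protocol: 5-fold CV, PCA components
    covering >95% of variance, differential screen at FDR < 0.01, removal
    of features with >30% missing values, K=5 imputation donors, classes
    kept only above 100 samples, and unit MFMD weights.
    """

    seed: int = 0
    n_folds: int = 5
    variance_target: float = 0.95
    fdr_threshold: float = 0.01
    missing_frac_max: float = 0.30
    impute_k: int = 5
    min_class_size: int = 100
    w_s: float = 1.0
    w_d: float = 1.0
    classifier_params: dict[str, dict] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLASSIFIER_PARAMS.items()}
    )

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError(f"n_folds must be >= 2, got {self.n_folds}")
        if self.impute_k < 1:
            raise ValueError(f"impute_k must be >= 1, got {self.impute_k}")
        if self.min_class_size < 1:
            raise ValueError(f"min_class_size must be >= 1, got {self.min_class_size}")
        _check_fraction("variance_target", self.variance_target)
        _check_fraction("fdr_threshold", self.fdr_threshold)
        _check_fraction("missing_frac_max", self.missing_frac_max, closed_low=True)
        _check_fraction("w_s", self.w_s)
        _check_fraction("w_d", self.w_d)

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["classifier_params"] = {
            k: {kk: (list(vv) if isinstance(vv, tuple) else vv) for kk, vv in v.items()}
            for k, v in d["classifier_params"].items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def derive_seed(seed: int, stage: str) -> int:
    """Deterministically derive a stage-specific 31-bit seed from the
    global one, so stages are decoupled yet reproducible."""
    ss = np.random.SeedSequence([seed, int.from_bytes(stage.encode(), "little") % (2**32)])
    return int(ss.generate_state(1)[0] % (2**31))


def rng_for(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(seed, stage))
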