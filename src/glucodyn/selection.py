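"""AIC/BIC model-structure selection.

Under the i.i.d. Gaussian error model the maximized log-likelihood is a
function of the minimized sum of squares alone, so both criteria are
computed on the Gaussian-profile scale (constants that cancel in model
differences are dropped):

    AIC = n * ln(SS/n) + 2k          BIC = k * ln(n) + n * ln(SS/n)

with ``n`` data points, ``k`` fitted parameters and ``SS`` the best sum of
squares found for the model.  ``mode="likelihood"`` restores the full
``-2 ln L`` constant ``n*(ln(2*pi) + 1)``; differences between models are
identical in both modes.

Two candidate structures fitted to the same dataset are compared through
``delta = IC(model 2) - IC(model 1)``.  Following the usual evidence
convention, the verdict is "substantial difference" only when both |ΔAIC|
and |ΔBIC| reach the threshold of 2; otherwise the models are reported as
"equally capable".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "ModelFit",
    "ComparisonRow",
    "SelectionReport",
    "VERDICT_EQUAL",
    "VERDICT_SUBSTANTIAL",
    "DELTA_THRESHOLD",
    "compute_aic",
    "compute_bic",
    "compare_models",
]

VERDICT_EQUAL = "equally capable"
VERDICT_SUBSTANTIAL = "substantial difference"
#: information-criterion difference read as substantial evidence
DELTA_THRESHOLD = 2.0

_GAUSS_CONST = math.log(2.0 * math.pi) + 1.0


def _check(n: int, k: int, ss: float) -> None:
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    if ss < 0:
        raise ValueError("SS must be >= 0")
    if ss == 0:
        raise ValueError("SS = 0: information criteria undefined for a perfect fit")


def compute_aic(n: int, k: int, ss: float, mode: str = "profile") -> float:
    """Akaike information criterion from the minimized sum of squares."""
    _check(n, k, ss)
    base = n * math.log(ss / n) + 2 * k
    if mode == "profile":
        return base
    if mode == "likelihood":
        return base + n * _GAUSS_CONST
    raise ValueError(f"unknown mode {mode!r}; expected 'profile' or 'likelihood'")


def compute_bic(n: int, k: int, ss: float, mode: str = "profile") -> float:
    """Bayesian information criterion from the minimized sum of squares."""
    _check(n, k, ss)
    base = k * math.log(n) + n * math.log(ss / n)
    if mode == "profile":
        return base
    if mode == "likelihood":
        return base + n * _GAUSS_CONST
    raise ValueError(f"unknown mode {mode!r}; expected 'profile' or 'likelihood'")


@dataclass(frozen=True)
class ModelFit:
    """Minimal description of one fitted model on one dataset."""

    model_id: int
    n: int  # number of data points
    k: int  # number of fitted parameters
    ss: float  # best (minimum) sum of squares
    dataset_id: Optional[str] = None  # used to guard against mismatched data

    def aic(self, mode: str = "profile") -> float:
        return compute_aic(self.n, self.k, self.ss, mode)

    def bic(self, mode: str = "profile") -> float:
        return compute_bic(self.n, self.k, self.ss, mode)


@dataclass(frozen=True)
class ComparisonRow:
    """Pairwise AIC/BIC comparison of two fits on one dataset."""

    dataset_id: Optional[str]
    n: int
    aic1: float
    bic1: float
    aic2: float
    bic2: float
    delta_aic: float  # AIC(model 2) - AIC(model 1)
    delta_bic: float
    verdict: str

    @property
    def preferred_model(self) -> int:
        return 1 if self.delta_aic > 0 else 2


def compare_models(fit1: ModelFit, fit2: ModelFit,
                   mode: str = "profile",
                   threshold: float = DELTA_THRESHOLD) -> ComparisonRow:
    """Compare two model structures fitted to the identical dataset.

    ``delta = IC(fit2) - IC(fit1)``; positive values favour the first
    model.  The verdict is ``"substantial difference"`` iff both |ΔAIC|
    and |ΔBIC| are at or above ``threshold``.
    """
    if fit1.n != fit2.n:
        raise ValueError("fits compare different numbers of data points")
    if (fit1.dataset_id is not None and fit2.dataset_id is not None
            and fit1.dataset_id != fit2.dataset_id):
        raise ValueError("fits were computed on different datasets")
    aic1, bic1 = fit1.aic(mode), fit1.bic(mode)
    aic2, bic2 = fit2.aic(mode), fit2.bic(mode)
    delta_aic = aic2 - aic1
    delta_bic = bic2 - bic1
    substantial = abs(delta_aic) >= threshold and abs(delta_bic) >= threshold
    return ComparisonRow(
        dataset_id=fit1.dataset_id or fit2.dataset_id,
        n=fit1.n, aic1=aic1, bic1=bic1, aic2=aic2, bic2=bic2,
        delta_aic=delta_aic, delta_bic=delta_bic,
        verdict=VERDICT_SUBSTANTIAL if substantial else VERDICT_EQUAL,
    )


@dataclass
class SelectionReport:
    """A table of pairwise comparisons, one row per dataset."""

    rows: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"dataset": r.dataset_id, "n": r.n,
              "AIC1": r.aic1, "BIC1": r.bic1, "AIC2": r.aic2, "BIC2": r.bic2,
              "dAIC": r.delta_aic, "dBIC": r.delta_bic, "verdict": r.verdict}
             for r in self.rows]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_fits(cls, pairs: Iterable[tuple[ModelFit, ModelFit]],
                  mode: str = "profile") -> "SelectionReport":
        return cls(rows=[compare_models(f1, f2, mode) for f1, f2 in pairs])
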