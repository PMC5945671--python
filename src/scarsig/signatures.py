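"""Supervised decomposition of mutational catalogues into known signatures.

A catalogue column is decomposed into a non-negative linear combination of a
fixed signature matrix by non-negative least squares. To raise specificity the
fit is run twice: signatures whose first-pass relative exposure does not
exceed a signature-specific cutoff are removed and the remaining set is
refitted. Cutoffs can be calibrated by ROC analysis on a labeled cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .catalogue import CHANNELS

__all__ = [
    "SignatureSet",
    "ExposureMatrix",
    "nnls_decompose",
    "supervised_exposures",
    "cohort_exposures",
    "calibrate_cutoffs",
    "min_load_filter",
]


@dataclass
class SignatureSet:
    """A 96 x k column-stochastic signature matrix with per-signature cutoffs."""

    W: np.ndarray
    names: list[str]
    cutoffs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != 96:
            raise ValueError(f"signature matrix must be 96 x k, got {self.W.shape}")
        if len(self.names) != self.W.shape[1]:
            raise ValueError("number of names does not match number of columns")
        if np.any(self.W < 0):
            raise ValueError("signature matrix must be non-negative")
        colsums = self.W.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-3):
            raise ValueError("signature columns must sum to 1 (within 1e-3)")
        if np.any(np.abs(colsums - 1.0) > 1e-12):  # keep W bit-stable once normalized
            self.W = self.W / colsums
        if self.cutoffs is None:
            self.cutoffs = np.zeros(self.k)
        self.cutoffs = np.asarray(self.cutoffs, dtype=float)
        if self.cutoffs.shape != (self.k,):
            raise ValueError("cutoffs must have one entry per signature")
        if np.any(self.cutoffs < 0) or np.any(self.cutoffs >= 1):
            raise ValueError("cutoffs must lie in [0, 1)")

    @property
    def k(self) -> int:
        return self.W.shape[1]

    def with_cutoffs(self, cutoffs: Sequence[float]) -> "SignatureSet":
        return SignatureSet(self.W.copy(), list(self.names), np.asarray(cutoffs, float))

    def subset(self, keep: np.ndarray) -> "SignatureSet":
        return SignatureSet(
            self.W[:, keep], [self.names[i] for i in np.flatnonzero(keep)],
            self.cutoffs[keep],
        )


@dataclass
class ExposureMatrix:
    """Signature exposures per sample, absolute (counts) and column-normalized."""

    H: pd.DataFrame                 # k x m, mutation-count units
    residuals: pd.Series            # per-sample residual norm of the final fit

    @property
    def relative(self) -> pd.DataFrame:
        totals = self.H.sum(axis=0)
        rel = self.H.div(totals.where(totals > 0, 1.0), axis=1)
        rel.loc[:, totals <= 0] = 0.0
        return rel

    @property
    def presence(self) -> pd.DataFrame:
        return self.H > 0


def nnls_decompose(v: np.ndarray, signatures: SignatureSet) -> tuple[np.ndarray, float]:
    """Non-negative least-squares fit of a 96-vector; returns (h, residual norm)."""
    v = np.asarray(v, dtype=float)
    if v.shape != (96,):
        raise ValueError(f"expected a 96-vector, got shape {v.shape}")
    if np.any(np.isnan(v)) or np.any(v < 0):
        raise ValueError("catalogue vector must be non-negative and finite")
    h, rnorm = nnls(signatures.W, v)
    return h, float(rnorm)


def supervised_exposures(
    v: np.ndarray, signatures: SignatureSet
) -> tuple[np.ndarray, float]:
    """Two-pass NNLS with signature-specific relative-exposure cutoffs.

    Pass 1 fits all signatures; signatures whose relative exposure
    (h_i / sum h) is not strictly above their cutoff are discarded (exposure
    set to exactly 0) and the surviving set is refitted in pass 2.
    """
    h1, rnorm1 = nnls_decompose(v, signatures)
    total = h1.sum()
    if total <= 0:
        return np.zeros(signatures.k), rnorm1
    keep = (h1 / total) > signatures.cutoffs
    if not np.any(keep):
        return np.zeros(signatures.k), float(np.linalg.norm(v))
    if np.all(keep):
        return h1, rnorm1
    h2, rnorm2 = nnls(signatures.W[:, keep], np.asarray(v, float))
    h = np.zeros(signatures.k)
    h[keep] = h2
    return h, float(rnorm2)


def cohort_exposures(catalogue: pd.DataFrame, signatures: SignatureSet) -> ExposureMatrix:
    """Column-wise supervised exposures for a whole catalogue."""
    if catalogue.shape[0] != 96:
        raise ValueError(f"catalogue must have 96 rows, got {catalogue.shape[0]}")
    if list(catalogue.index) != list(CHANNELS):
        if set(catalogue.index) == set(CHANNELS):
            catalogue = catalogue.loc[list(CHANNELS)]
        else:
            raise ValueError("catalogue rows do not match the 96 canonical channels")
    H = np.zeros((signatures.k, catalogue.shape[1]))
    resid = np.zeros(catalogue.shape[1])
    for j, sample in enumerate(catalogue.columns):
        H[:, j], resid[j] = supervised_exposures(catalogue[sample].to_numpy(), signatures)
    return ExposureMatrix(
        H=pd.DataFrame(H, index=signatures.names, columns=catalogue.columns),
        residuals=pd.Series(resid, index=catalogue.columns, name="residual"),
    )


def _pass1_relative(catalogue: pd.DataFrame, signatures: SignatureSet) -> np.ndarray:
    rel = np.zeros((signatures.k, catalogue.shape[1]))
    for j in range(catalogue.shape[1]):
        h, _ = nnls_decompose(catalogue.iloc[:, j].to_numpy(), signatures)
        t = h.sum()
        if t > 0:
            rel[:, j] = h / t
    return rel


def calibrate_cutoffs(
    training_catalogue: pd.DataFrame,
    truth: np.ndarray,
    signatures: SignatureSet,
) -> np.ndarray:
    """Per-signature cutoffs maximizing Youden's J on a labeled training cohort.

    ``truth`` is a k x m boolean presence matrix aligned to the training
    samples. Candidate cutoffs are swept over the observed first-pass relative
    exposures; ties are broken toward the larger cutoff. A signature whose
    truth labels are single-class gets cutoff 0 with a warning.
    """
    truth = np.asarray(truth, dtype=bool)
    if truth.shape != (signatures.k, training_catalogue.shape[1]):
        raise ValueError("truth matrix must be k x m, aligned to training samples")
    rel = _pass1_relative(training_catalogue, signatures)
    cutoffs = np.zeros(signatures.k)
    for i in range(signatures.k):
        pos, neg = truth[i], ~truth[i]
        if not pos.any() or not neg.any():
            warnings.warn(
                f"signature {signatures.names[i]}: single-class truth, cutoff set to 0",
                stacklevel=2,
            )
            continue
        candidates = np.unique(np.concatenate([[0.0], rel[i]]))
        best_j, best_c = -np.inf, 0.0
        for c in candidates:
            called = rel[i] > c
            sens = (called & pos).sum() / pos.sum()
            spec = (~called & neg).sum() / neg.sum()
            j = sens + spec - 1.0
            if j > best_j or (j == best_j and c > best_c):
                best_j, best_c = j, c
        cutoffs[i] = best_c
    return cutoffs


def min_load_filter(catalogue: pd.DataFrame, min_snvs: int = 25) -> pd.DataFrame:
    """Drop samples whose total SNV count is not strictly above ``min_snvs``."""
    keep = catalogue.sum(axis=0) > min_snvs
    return catalogue.loc[:, keep]
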