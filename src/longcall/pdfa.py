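"""Crossed permuted discriminant function analysis (pDFA).

Tests whether a categorical *test factor* (e.g. sub-pulse type) is
acoustically distinct while controlling for a *control factor* (e.g.
individual identity) whose levels each contain several test-factor levels —
a crossed design.  Repeated-measures data make a plain DFA anti-conservative
(pseudoreplication); the pDFA addresses this in two ways:

* **Balanced selection** — per control level, the same number of cases is
  drawn from every test level (the smallest cell count in that level), the
  DFA is fitted on the selected cases, and classification accuracy is
  recorded both on the selected cases (resubstitution) and on the held-out
  remainder (cross-classification).  Averaging over ``n_sel`` random
  selections removes selection noise.
* **Restricted permutation** — the null distribution is built by shuffling
  test-factor labels *only within* control-factor levels, so identity
  structure is preserved exactly; one selection/DFA cycle is run per
  permutation.

The p-value uses the add-one convention, counting the observed value as one
permutation, so the smallest attainable p with ``n_perm`` permutations is
1/(n_perm + 1).  The expected (chance) accuracy is the mean of the null
distribution, which properly exceeds 1/k for unbalanced designs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .errors import DesignError, InsufficientDataError, ModelError
from .tables_io import ACOUSTIC_MEASURES

log = logging.getLogger(__name__)

#: Column synonyms for the seven acoustic measures (Raven-style names).
VARIABLE_SYNONYMS: dict[str, str] = {
    "Delta.Time": "duration",
    "Peak.Freq": "peak_frequency",
    "Peak.Time": "peak_time",
    "PFC.Avg.Slope": "pfc_avg_slope",
    "PFC.Max.Slope": "pfc_max_slope",
    "Avg.Entropy": "avg_entropy",
    "SNR.NIST.Quick": "snr_nist_quick",
}


@dataclass
class PDFAConfig:
    """Configuration of a crossed pDFA run."""

    test_factor: str = "sub_type"
    control_factor: str = "individual_id"
    variables: tuple[str, ...] = ACOUSTIC_MEASURES
    n_sel: int = 100
    n_perm: int = 1000
    n_to_sel: int | None = None   # cap on the per-level balanced selection size
    seed: int | None = None
    standardize: bool = False
    ridge: float | None = None    # LDA shrinkage for ill-conditioned covariance

    def __post_init__(self) -> None:
        if self.n_sel < 1:
            raise ValueError("n_sel must be >= 1")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100 for a usable null")
        if not self.variables:
            raise ValueError("variables must be nonempty")


@dataclass
class PDFAResult:
    """Observed and permutation-null classification percentages."""

    observed_pct_selected: float
    observed_pct_cross: float
    expected_pct: float
    p_value: float
    null_distribution: np.ndarray
    n_sel: int
    n_perm: int
    n_cases: int
    selection_size: dict[str, int]     # balanced size per control level
    dropped_cells: list[tuple[str, str, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "observed_pct_selected": self.observed_pct_selected,
            "observed_pct_cross": self.observed_pct_cross,
            "expected_pct": self.expected_pct,
            "p_value": self.p_value,
            "n_sel": self.n_sel,
            "n_perm": self.n_perm,
            "n_cases": self.n_cases,
            "selection_size": self.selection_size,
            "dropped_cells": [list(c) for c in self.dropped_cells],
        }


def fit_lda(X: np.ndarray, y: np.ndarray,
            ridge: float | None = None) -> LinearDiscriminantAnalysis:
    """Fit a Fisher linear discriminant with pooled within-class covariance.

    Priors are proportional to class frequencies.  Requires at least two
    classes with two cases each and finite features.  If the pooled
    within-class covariance is numerically singular, raises with advice to
    drop variables or pass a ``ridge`` (shrinkage) term, which switches to
    the least-squares solver with that shrinkage.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ModelError("LDA features must be finite")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise InsufficientDataError("LDA needs >= 2 classes")
    if counts.min() < 2:
        raise InsufficientDataError(
            f"every class needs >= 2 cases; got {dict(zip(classes, counts))}")
    if ridge is not None:
        model = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=ridge)
        return model.fit(X, y)
    # centre within class and check the pooled scatter is full rank
    Xc = X - np.vstack([X[y == c].mean(axis=0) for c in classes])[
        np.searchsorted(classes, y)]
    s = np.linalg.svd(Xc, compute_uv=False)
    if s[0] <= 0 or s[-1] / s[0] < 1e-10:
        raise ModelError(
            "pooled within-class covariance is singular; drop collinear "
            "variables or pass ridge=<shrinkage in (0, 1]>")
    return LinearDiscriminantAnalysis(solver="svd").fit(X, y)


def permute_within_blocks(rng: np.random.Generator, labels: np.ndarray,
                          blocks: np.ndarray) -> np.ndarray:
    """Shuffle ``labels`` independently inside each block of ``blocks``.

    The multiset of labels within every block is preserved exactly — no label
    ever crosses a block (control-factor) boundary.
    """
    labels = np.asarray(labels)
    out = labels.copy()
    for b in np.unique(blocks):
        idx = np.where(blocks == b)[0]
        out[idx] = labels[idx[rng.permutation(len(idx))]]
    return out


def _prepare(data: pd.DataFrame, config: PDFAConfig):
    df = data.rename(columns=VARIABLE_SYNONYMS).copy()
    missing = [v for v in config.variables if v not in df.columns]
    if missing:
        raise DesignError(f"acoustic table is missing variable column(s) {missing}")
    for fac in (config.test_factor, config.control_factor):
        if fac not in df.columns:
            raise DesignError(f"acoustic table is missing factor column '{fac}'")
    df = df.dropna(subset=list(config.variables))
    X = df[list(config.variables)].to_numpy(float)
    if config.standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    y = df[config.test_factor].astype(str).to_numpy()
    blocks = df[config.control_factor].astype(str).to_numpy()

    # drop cells with < 2 cases, then control levels with < 2 test levels
    dropped: list[tuple[str, str, int]] = []
    keep = np.ones(len(df), dtype=bool)
    cells = pd.Series(1, index=pd.MultiIndex.from_arrays([blocks, y])) \
        .groupby(level=[0, 1]).sum()
    for (b, t), n in cells.items():
        if n < 2:
            dropped.append((b, t, int(n)))
            keep &= ~((blocks == b) & (y == t))
    if dropped:
        log.warning("pDFA: dropping %d cell(s) with < 2 cases: %s",
                    len(dropped), dropped)
    X, y, blocks = X[keep], y[keep], blocks[keep]
    for b in np.unique(blocks):
        if len(np.unique(y[blocks == b])) < 2:
            mask = blocks != b
            X, y, blocks = X[mask], y[mask], blocks[mask]
            log.warning("pDFA: dropping control level '%s' with < 2 test levels", b)
    if len(np.unique(y)) < 2 or len(X) == 0:
        usable = sorted(set(zip(blocks, y)))
        raise DesignError(
            f"crossed design needs >= 2 test levels with >= 2 cases inside "
            f"some control level; usable cells: {usable}")
    return X, y, blocks, dropped


def _selection_sizes(y, blocks, cap: int | None) -> dict[str, int]:
    sizes = {}
    for b in np.unique(blocks):
        counts = pd.Series(y[blocks == b]).value_counts()
        m = int(counts.min())
        sizes[str(b)] = min(m, cap) if cap else m
    return sizes


def _one_cycle(rng, X, y, blocks, sizes, ridge):
    """One balanced selection + DFA; returns (% correct selected, % cross)."""
    sel_idx = []
    for b, m in sizes.items():
        bmask = blocks == b
        for t in np.unique(y[bmask]):
            cell = np.where(bmask & (y == t))[0]
            sel_idx.append(rng.choice(cell, size=min(m, len(cell)), replace=False))
    sel = np.concatenate(sel_idx)
    rest = np.setdiff1d(np.arange(len(y)), sel)
    model = fit_lda(X[sel], y[sel], ridge=ridge)
    pct_sel = 100.0 * float(np.mean(model.predict(X[sel]) == y[sel]))
    pct_cross = 100.0 * float(np.mean(model.predict(X[rest]) == y[rest])) \
        if len(rest) else float("nan")
    return pct_sel, pct_cross


def pdfa_crossed(data: pd.DataFrame, config: PDFAConfig,
                 rng: np.random.Generator | None = None) -> PDFAResult:
    """Run the crossed permuted discriminant function analysis.

    ``data`` holds one row per case with the acoustic variable columns
    (Raven-style synonyms accepted) plus test- and control-factor columns.
    With ``config.seed`` set (and no external ``rng``) the entire result is
    reproducible bit for bit.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    X, y, blocks, dropped = _prepare(data, config)
    sizes = _selection_sizes(y, blocks, config.n_to_sel)

    obs_sel = np.empty(config.n_sel)
    obs_cross = np.empty(config.n_sel)
    for i in range(config.n_sel):
        obs_sel[i], obs_cross[i] = _one_cycle(rng, X, y, blocks, sizes,
                                              config.ridge)
    observed = float(np.mean(obs_sel))
    # the holdout can be empty when every cell has exactly the minimum size
    observed_cross = float(np.nanmean(obs_cross)) \
        if not np.all(np.isnan(obs_cross)) else float("nan")

    null = np.empty(config.n_perm)
    for j in range(config.n_perm):
        y_perm = permute_within_blocks(rng, y, blocks)
        null[j], _ = _one_cycle(rng, X, y_perm, blocks, sizes, config.ridge)
    p = (1.0 + float(np.sum(null >= observed))) / (config.n_perm + 1.0)

    return PDFAResult(
        observed_pct_selected=observed,
        observed_pct_cross=observed_cross,
        expected_pct=float(np.mean(null)),
        p_value=p,
        null_distribution=null,
        n_sel=config.n_sel,
        n_perm=config.n_perm,
        n_cases=len(y),
        selection_size=sizes,
        dropped_cells=dropped,
    )
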