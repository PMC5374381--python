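"""PCA of word-frequency matrices and load-factor reports.

The fit is on mean-centred columns with no variance scaling: all
features live on the same frequency scale, and unit-variance scaling
would inflate rare-word noise.  Components are ordered by decreasing
variance and each loading column is sign-flipped so its largest-
magnitude entry is positive, which makes scores, loadings and plots
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA

from ._errors import ConfigurationError, DegenerateInputError
from .composition import FrequencyMatrix, gc_class_of


@dataclass
class PCAResult:
    read_ids: list[str]
    words: tuple[str, ...]
    scores: np.ndarray              # reads x n_components
    loadings: np.ndarray            # features x n_components, unit columns
    variance_explained: np.ndarray  # fractions, non-increasing
    column_means: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def scores_to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\t" + "\t".join(
                f"PC{i + 1}" for i in range(self.n_components)) + "\n")
            for rid, row in zip(self.read_ids, self.scores):
                fh.write(rid + "\t" + "\t".join("%.17g" % v for v in row) + "\n")


def fit_pca(matrix: FrequencyMatrix, n_components: int = 2) -> PCAResult:
    """Principal components of the read x feature matrix."""
    X = matrix.values
    n, k = X.shape
    if n < 2:
        raise DegenerateInputError("PCA needs at least 2 reads")
    if not 1 <= n_components <= min(n - 1, k):
        raise ConfigurationError(
            f"n_components={n_components} out of range for a {n}x{k} matrix"
        )
    centred = X - X.mean(axis=0)
    if not np.any(np.abs(centred) > 1e-15):
        raise DegenerateInputError("matrix has zero total variance")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T.copy()
    # deterministic sign: largest-|value| entry of each column positive
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAResult(
        read_ids=list(matrix.read_ids),
        words=matrix.features.words,
        scores=scores,
        loadings=loadings,
        variance_explained=pca.explained_variance_ratio_.copy(),
        column_means=pca.mean_.copy(),
    )


@dataclass
class LoadFactorEntry:
    word: str
    load_factor: float
    gc_class: str


@dataclass
class LoadFactorReport:
    """Top-m positive then bottom-m negative loadings of one component."""

    component: int
    m: int
    entries: list[LoadFactorEntry]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("word\tload_factor\tgc_class\n")
            for e in self.entries:
                fh.write(f"{e.word}\t{'%.17g' % e.load_factor}\t{e.gc_class}\n")


def load_factor_report(pca: PCAResult, component: int = 0, m: int = 20) -> LoadFactorReport:
    """The m largest and m smallest load factors of a fitted component.

    The positive block is sorted descending, the negative block
    ascending (most negative first); each entry is annotated with the
    word's GC class for plot colouring.
    """
    if not 0 <= component < pca.n_components:
        raise ConfigurationError(f"component {component} not fitted")
    loads = pca.loadings[:, component]
    if m > len(loads) // 2:
        raise ConfigurationError(f"m={m} exceeds half the feature count")
    order = np.argsort(-loads, kind="stable")
    top = order[:m]
    bottom = order[-m:][::-1]  # ascending: most negative first
    entries = [
        LoadFactorEntry(pca.words[i], float(loads[i]), gc_class_of(pca.words[i]))
        for i in np.concatenate([top, bottom])
    ]
    return LoadFactorReport(component=component, m=m, entries=entries)
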