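"""Pairwise Pearson correlations, Fisher z averaging and wedge z-tests.

Correlation coefficients are not additive, so per-pair r values are
mapped to Fisher z = ln((1+r)/(1-r))/2 = artanh(r), averaged
arithmetically, and the mean is mapped back with R = tanh(mean z).
r is clipped to +/-(1 - 1e-7) before the transform so identical reads
(legitimately common when deduplication is off) keep z finite.

The inner-vs-outer wedge comparison is an unpooled two-sample z test on
the Fisher-z samples.  Pairwise correlations sharing a read are not
independent; the test mirrors the construction used in practice and
uses the pair count as the sample size — a documented approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from ._errors import ConfigurationError, DegenerateInputError

logger = logging.getLogger(__name__)

R_CLAMP = 1.0 - 1e-7

CellLabel = tuple[str, str]  # (group, sample)


def pearson(u: np.ndarray, v: np.ndarray) -> float:
    """Product-moment correlation of two equal-length vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or len(u) < 2:
        raise ConfigurationError("pearson needs two equal-length vectors of length >= 2")
    du = u - u.mean()
    dv = v - v.mean()
    su = np.sqrt(du @ du)
    sv = np.sqrt(dv @ dv)
    if su == 0.0 or sv == 0.0:
        raise DegenerateInputError("constant vector has undefined correlation")
    return float((du @ dv) / (su * sv))


def fisher_z(r):
    """Fisher z = artanh(r), after clamping |r| to 1 - 1e-7."""
    return np.arctanh(np.clip(r, -R_CLAMP, R_CLAMP))


def fisher_inverse(z):
    """Back-transform R = tanh(z)."""
    return np.tanh(z)


@dataclass
class CorrelationSummary:
    """Fisher-mean correlation between two (group, sample) cells.

    ``z_values`` is the per-pair Fisher-z sample retained for the wedge
    significance test; it is dropped on JSON serialization.
    """

    cell_a: CellLabel
    cell_b: CellLabel
    n_pairs: int
    mean_R: float
    z_values: Optional[np.ndarray] = None
    subsampled: bool = False
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "cell_a": list(self.cell_a),
            "cell_b": list(self.cell_b),
            "n_pairs": self.n_pairs,
            "mean_R": self.mean_R,
            "subsampled": self.subsampled,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CorrelationSummary":
        return cls(
            cell_a=tuple(d["cell_a"]),
            cell_b=tuple(d["cell_b"]),
            n_pairs=d["n_pairs"],
            mean_R=d["mean_R"],
            z_values=None,
            subsampled=d.get("subsampled", False),
            seed=d.get("seed"),
        )


def _standardize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-standardized copy plus a keep-mask excluding constant rows."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    keep = sd[:, 0] > 0.0
    Z = np.zeros_like(X)
    Z[keep] = (X[keep] - mu[keep]) / sd[keep]
    return Z / np.sqrt(X.shape[1]), keep


def mean_correlation(
    cell_a: np.ndarray,
    cell_b: np.ndarray,
    same_cell: bool = False,
    max_pairs: int = 200_000,
    seed: int = 0,
    label_a: CellLabel = ("", ""),
    label_b: CellLabel = ("", ""),
) -> CorrelationSummary:
    """Fisher-mean correlation over all read pairs between two cells.

    Different cells contribute the full Cartesian product of pairs; a
    single cell (``same_cell=True``) contributes each unordered distinct
    pair once.  If the pair count exceeds ``max_pairs`` a uniform seeded
    subsample of exactly ``max_pairs`` pairs is used instead.
    """
    A = np.asarray(cell_a, dtype=float)
    B = A if same_cell else np.asarray(cell_b, dtype=float)
    if A.ndim != 2 or B.ndim != 2:
        raise ConfigurationError("cells must be 2-D (reads x features) arrays")
    Za, keep_a = _standardize_rows(A)
    Za = Za[keep_a]
    if same_cell:
        Zb = Za
        dropped = int((~keep_a).sum())
    else:
        Zb, keep_b = _standardize_rows(B)
        Zb = Zb[keep_b]
        dropped = int((~keep_a).sum() + (~keep_b).sum())
    if dropped:
        logger.info("mean_correlation: excluded %d constant-feature reads", dropped)
    na, nb = len(Za), len(Zb)
    if na < 2 or nb < 2:
        raise DegenerateInputError("each cell needs at least 2 usable vectors")

    total = na * (na - 1) // 2 if same_cell else na * nb
    subsampled = total > max_pairs
    if subsampled:
        rng = np.random.default_rng(seed)
        flat = rng.choice(total, size=max_pairs, replace=False)
        if same_cell:
            # map flat upper-triangle index -> (i, j), i < j
            i = (na - 2 - np.floor(
                np.sqrt(-8 * flat + 4 * na * (na - 1) - 7) / 2 - 0.5)).astype(int)
            j = (flat + i + 1 - i * (2 * na - i - 1) // 2).astype(int)
        else:
            i, j = np.divmod(flat, nb)
        r = np.einsum("ij,ij->i", Za[i], Zb[j])
    else:
        R = Za @ Zb.T
        if same_cell:
            iu = np.triu_indices(na, k=1)
            r = R[iu]
        else:
            r = R.ravel()
    z = fisher_z(r)
    return CorrelationSummary(
        cell_a=label_a,
        cell_b=label_b,
        n_pairs=len(z),
        mean_R=float(fisher_inverse(z.mean())),
        z_values=z,
        subsampled=subsampled,
        seed=seed if subsampled else None,
    )


@dataclass
class WedgeSignificance:
    """Two-sample z comparison of inner vs outer Fisher-z distributions."""

    inner_cellpair: str
    outer_cellpair: str
    z_score: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "inner_cellpair": self.inner_cellpair,
            "outer_cellpair": self.outer_cellpair,
            "z_score": self.z_score,
            "p_value": self.p_value,
        }


def _pair_name(s: CorrelationSummary) -> str:
    return f"{s.cell_a[0]}@{s.cell_a[1]}|{s.cell_b[0]}@{s.cell_b[1]}"


def wedge_significance(
    inner: CorrelationSummary, outer: CorrelationSummary
) -> WedgeSignificance:
    """Unpooled two-sided z test: positive z means inner exceeds outer."""
    if inner.z_values is None or outer.z_values is None:
        raise ConfigurationError("summaries must retain their z_values")
    zi, zo = inner.z_values, outer.z_values
    vi = zi.var(ddof=1) if len(zi) > 1 else 0.0
    vo = zo.var(ddof=1) if len(zo) > 1 else 0.0
    se = np.sqrt(vi / len(zi) + vo / len(zo))
    if se == 0.0:
        if zi.mean() == zo.mean():
            raise DegenerateInputError("both z samples are degenerate and identical")
        z_score = np.inf if zi.mean() > zo.mean() else -np.inf
    else:
        z_score = (zi.mean() - zo.mean()) / se
    p = float(2.0 * stats.norm.sf(abs(z_score)))
    return WedgeSignificance(
        inner_cellpair=_pair_name(inner),
        outer_cellpair=_pair_name(outer),
        z_score=float(z_score),
        p_value=p,
    )


def summaries_to_tsv(
    rows: Sequence[tuple[CorrelationSummary, Optional[WedgeSignificance]]],
    path,
) -> None:
    """Export summaries (with optional significance) as TSV."""
    with open(path, "w") as fh:
        fh.write("cell_a\tcell_b\tn_pairs\tmean_R\tz_score\tp_value\n")
        for summary, sig in rows:
            za = "%.17g" % sig.z_score if sig else ""
            pv = "%.17g" % sig.p_value if sig else ""
            fh.write(
                f"{summary.cell_a[0]}@{summary.cell_a[1]}\t"
                f"{summary.cell_b[0]}@{summary.cell_b[1]}\t"
                f"{summary.n_pairs}\t{'%.17g' % summary.mean_R}\t{za}\t{pv}\n"
            )
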