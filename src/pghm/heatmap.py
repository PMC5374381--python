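"""Assembly of the phylogenetic heatmap (PGHM) model.

The model is a two-ring "doughnut" over N phylogenetic groups shared by
two samples.  Each inner wedge holds the Fisher-mean correlation between
the SAME group's reads across the two samples; each group also gets two
outer wedges, one per sample, holding the correlation between that group
and its nearest (most correlated) different group within the sample.
A lighter inner ring than outer ring means reads cluster by phylogeny
(no composition bias between samples); a darker inner ring means reads
cluster by sample — the signature of composition bias.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ._errors import ConfigurationError, DegenerateInputError
from .composition import FrequencyMatrix
from .correlation_stats import (
    CorrelationSummary,
    WedgeSignificance,
    mean_correlation,
    wedge_significance,
)
from .decomposition import fit_pca
from .sequence_io import SampleSet

logger = logging.getLogger(__name__)

PATTERN_PHYLO = "phylogenetic_clustering"
PATTERN_SAMPLE = "sample_clustering"
PATTERN_MIXED = "mixed"


@dataclass
class PGHMConfig:
    nearest_method: str = "mean_correlation"   # or "pc_centroid"
    shade_scale: str = "fixed_unit"            # or "data_range"
    max_pairs: int = 200_000
    seed: int = 0


@dataclass
class Wedge:
    """One heatmap wedge; ``sample_label``/``nearest_group`` are None on
    inner wedges."""

    group: str
    summary: CorrelationSummary
    shade: float = 0.0
    sample_label: Optional[str] = None
    nearest_group: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "sample_label": self.sample_label,
            "nearest_group": self.nearest_group,
            "shade": self.shade,
            "summary": self.summary.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Wedge":
        return cls(
            group=d["group"],
            summary=CorrelationSummary.from_dict(d["summary"]),
            shade=d["shade"],
            sample_label=d.get("sample_label"),
            nearest_group=d.get("nearest_group"),
        )


@dataclass
class PGHMModel:
    n_groups: int
    groups: list[str]
    sample_labels: tuple[str, str]
    inner_wedges: list[Wedge]                 # one per group, group order
    outer_wedges: list[Wedge]                 # group-major, sample A then B
    significance: list[WedgeSignificance]     # 2N, group-major, A then B
    pattern: str
    shade_scale: str = "fixed_unit"

    def outer_pair(self, group: str) -> tuple[Wedge, Wedge]:
        pair = [w for w in self.outer_wedges if w.group == group]
        if len(pair) != 2:
            raise ConfigurationError(f"group {group!r} does not have 2 outer wedges")
        return pair[0], pair[1]

    def to_dict(self) -> dict:
        return {
            "n_groups": self.n_groups,
            "groups": self.groups,
            "sample_labels": list(self.sample_labels),
            "inner_wedges": [w.to_dict() for w in self.inner_wedges],
            "outer_wedges": [w.to_dict() for w in self.outer_wedges],
            "significance": [s.to_dict() for s in self.significance],
            "pattern": self.pattern,
            "shade_scale": self.shade_scale,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PGHMModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            n_groups=d["n_groups"],
            groups=d["groups"],
            sample_labels=tuple(d["sample_labels"]),
            inner_wedges=[Wedge.from_dict(w) for w in d["inner_wedges"]],
            outer_wedges=[Wedge.from_dict(w) for w in d["outer_wedges"]],
            significance=[
                WedgeSignificance(**s) for s in d["significance"]
            ],
            pattern=d["pattern"],
            shade_scale=d.get("shade_scale", "fixed_unit"),
        )


def select_groups(sample_a: SampleSet, sample_b: SampleSet, n: int = 4) -> list[str]:
    """The n most numerous groups shared by both samples.

    Ranking is by the smaller of the two per-sample counts (so both
    cells are populated), ties broken lexicographically; groups need at
    least 2 reads in each sample to qualify.
    """
    if n <= 1:
        raise ConfigurationError("n must be > 1")
    ca, cb = sample_a.group_counts(), sample_b.group_counts()
    shared = [g for g in ca if g in cb and ca[g] >= 2 and cb[g] >= 2]
    if len(shared) < n:
        raise ConfigurationError(
            f"need {n} shared groups with >=2 reads each; qualifying groups: "
            f"{sorted(shared)}"
        )
    shared.sort(key=lambda g: (-min(ca[g], cb[g]), g))
    return shared[:n]


def _cell(sample: SampleSet, group: str, matrix: FrequencyMatrix) -> np.ndarray:
    ids = [r.read_id for r in sample.assigned_reads(group)]
    return matrix.rows_for(ids)


def nearest_group(
    group: str,
    sample: SampleSet,
    candidates: Sequence[str],
    matrix: FrequencyMatrix,
    method: str = "mean_correlation",
    max_pairs: int = 200_000,
    seed: int = 0,
    pc_scores: Optional[dict[str, np.ndarray]] = None,
    check_agreement: bool = False,
) -> str:
    """The candidate group closest to ``group`` within its own sample.

    ``mean_correlation``: highest Fisher-mean cross-correlation.
    ``pc_centroid``: nearest centroid in the first-two-PC score space.
    Ties break lexicographically.  With ``check_agreement`` both methods
    run and a disagreement logs a warning (never an error).
    """
    others = sorted(c for c in candidates if c != group)
    if not others:
        raise ConfigurationError(f"no candidate groups besides {group!r}")
    if method not in ("mean_correlation", "pc_centroid"):
        raise ConfigurationError(f"unknown nearest-group method {method!r}")

    def by_correlation() -> str:
        best, best_R = None, -np.inf
        for cand in others:
            R = mean_correlation(
                _cell(sample, group, matrix), _cell(sample, cand, matrix),
                same_cell=False, max_pairs=max_pairs, seed=seed,
            ).mean_R
            if R > best_R:
                best, best_R = cand, R
        return best

    def by_centroid() -> str:
        if pc_scores is not None:
            centroids = pc_scores
        else:
            pca = fit_pca_cached(matrix)
            row = {rid: i for i, rid in enumerate(pca.read_ids)}
            centroids = {}
            for g in [group] + others:
                idx = [row[r.read_id] for r in sample.assigned_reads(g)
                       if r.read_id in row]
                centroids[g] = pca.scores[idx, :2].mean(axis=0)
        ref = centroids[group]
        dists = {c: float(np.linalg.norm(centroids[c] - ref)) for c in others}
        return min(others, key=lambda c: (dists[c], c))

    if method == "mean_correlation":
        result = by_correlation()
        if check_agreement:
            alt = by_centroid()
            if alt != result:
                logger.warning(
                    "nearest_group(%s): methods disagree (%s vs %s)",
                    group, result, alt)
    else:
        result = by_centroid()
        if check_agreement:
            alt = by_correlation()
            if alt != result:
                logger.warning(
                    "nearest_group(%s): methods disagree (%s vs %s)",
                    group, result, alt)
    logger.info("nearest_group(%s@%s, %s) = %s",
                group, sample.sample_label, method, result)
    return result


_pca_cache: dict[int, object] = {}


def fit_pca_cached(matrix: FrequencyMatrix):
    """Two-component PCA of a matrix, cached per matrix object."""
    key = id(matrix)
    if key not in _pca_cache:
        _pca_cache.clear()
        _pca_cache[key] = fit_pca(matrix, n_components=2)
    return _pca_cache[key]


def shade(
    mean_R: float,
    scale: str = "fixed_unit",
    data_min: Optional[float] = None,
    data_max: Optional[float] = None,
) -> float:
    """Gray level in [0, 1] for a wedge; darker always means lower R.

    ``fixed_unit`` maps [0, 1] linearly (values clipped); ``data_range``
    maps linearly over the model's own wedge-mean range.
    """
    if not np.isfinite(mean_R):
        raise ConfigurationError("mean_R must be finite")
    if scale == "fixed_unit":
        return float(np.clip(mean_R, 0.0, 1.0))
    if scale == "data_range":
        if data_min is None or data_max is None:
            raise ConfigurationError("data_range shading needs data_min/data_max")
        if data_max <= data_min:
            return 0.5
        return float(np.clip((mean_R - data_min) / (data_max - data_min), 0.0, 1.0))
    raise ConfigurationError(f"unknown shade scale {scale!r}")


def build_pghm(
    sample_a: SampleSet,
    sample_b: SampleSet,
    matrix: FrequencyMatrix,
    n: int = 4,
    config: Optional[PGHMConfig] = None,
) -> PGHMModel:
    """Compute inner/outer wedges, shades, significance and the pattern.

    ``matrix`` must contain the featurized reads of both samples
    (a shared feature space; see :meth:`FrequencyMatrix.concat`).
    """
    cfg = config or PGHMConfig()
    groups = select_groups(sample_a, sample_b, n)
    la, lb = sample_a.sample_label, sample_b.sample_label
    if la == lb:
        raise ConfigurationError("the two samples must have distinct labels")

    inner: list[Wedge] = []
    outer: list[Wedge] = []
    sigs: list[WedgeSignificance] = []
    for g in groups:
        s_inner = mean_correlation(
            _cell(sample_a, g, matrix), _cell(sample_b, g, matrix),
            same_cell=False, max_pairs=cfg.max_pairs, seed=cfg.seed,
            label_a=(g, la), label_b=(g, lb),
        )
        inner.append(Wedge(group=g, summary=s_inner))
        for sample in (sample_a, sample_b):
            nn = nearest_group(
                g, sample, groups, matrix,
                method=cfg.nearest_method, max_pairs=cfg.max_pairs, seed=cfg.seed,
            )
            s_outer = mean_correlation(
                _cell(sample, g, matrix), _cell(sample, nn, matrix),
                same_cell=False, max_pairs=cfg.max_pairs, seed=cfg.seed,
                label_a=(g, sample.sample_label), label_b=(nn, sample.sample_label),
            )
            outer.append(Wedge(
                group=g, summary=s_outer,
                sample_label=sample.sample_label, nearest_group=nn,
            ))
            sigs.append(wedge_significance(s_inner, s_outer))

    all_R = [w.summary.mean_R for w in inner + outer]
    lo, hi = min(all_R), max(all_R)
    for w in inner + outer:
        w.shade = shade(w.summary.mean_R, cfg.shade_scale, lo, hi)

    votes = []
    for i, g in enumerate(groups):
        ri = inner[i].summary.mean_R
        ra, rb = (w.summary.mean_R for w in (outer[2 * i], outer[2 * i + 1]))
        votes.append("phylo" if ri > max(ra, rb)
                     else "sample" if ri < min(ra, rb) else "mixed")
    if all(v == "phylo" for v in votes):
        pattern = PATTERN_PHYLO
    elif all(v == "sample" for v in votes):
        pattern = PATTERN_SAMPLE
    else:
        pattern = PATTERN_MIXED

    return PGHMModel(
        n_groups=n,
        groups=groups,
        sample_labels=(la, lb),
        inner_wedges=inner,
        outer_wedges=outer,
        significance=sigs,
        pattern=pattern,
        shade_scale=cfg.shade_scale,
    )
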