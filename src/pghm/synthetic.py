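"""Synthetic two-sample amplicon generator with controlled bias.

The generator emulates a pair of amplicon sequencing runs over the same
community: N group templates of amplicon length with distinct GC
content, per-read point-mutation noise, and an optional sample-level
platform bias.  Bias has three knobs:

* ``gc_shift`` — a systematic composition shift.  Sequencing-platform
  composition bias is reproducible: specific local sequence contexts
  (e.g. homopolymer runs on 454) are miscalled the same way in every
  read.  The shift is therefore modelled as a per-sample rule mapping
  A/T-centred 5-mer contexts to a fixed G/C replacement (or G/C-centred
  to A/T when the shift is negative), with vulnerable contexts selected
  under an occurrence-weighted quota so the realized flipped fraction of
  eligible bases matches ``|gc_shift|``.  Random, read-independent noise
  is the role of ``mutation_rate``, not of the bias.
* ``gc_dropout`` — logistic read retention by GC%, emulating
  coverage bias against GC-poor or GC-rich fragments.
* ``homopolymer_noise`` — per-run probability of a +/-1 length error at
  homopolymer runs of length >= 3.

Group sizes are exact: dropout rejection-samples until the requested
read count is met (with a retry cap), keeping pair counts stable across
scenarios.

Default scenario conditions emulate species-level taxa within one
hypervariable region: templates 250 nt, 2% inter-group divergence and a
1.5% GC spread (16S regions of congeneric species are typically 95-99%
identical), 200 reads per group, 1% per-base read noise, constant
Phred 38 qualities.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ._errors import ConfigurationError, DegenerateInputError
from .sequence_io import ReadRecord, SampleSet, write_fastq, write_group_table

logger = logging.getLogger(__name__)

BASES = "ACGT"

DEFAULT_GROUP_NAMES = (
    "alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta",
)

SCENARIOS = ("positive_control", "negative_control", "platform_bias")


@dataclass(frozen=True)
class BiasModel:
    """Sample-level platform bias; the all-zero default is no bias."""

    gc_shift: float = 0.0            # signed flipped fraction of A/T (or G/C) bases
    dropout_slope: float = 0.0       # logistic slope on GC fraction; 0 = off
    dropout_midpoint: float = 0.5    # GC fraction of 50% retention
    homopolymer_noise: float = 0.0   # per-run +/-1 length error probability

    def __post_init__(self) -> None:
        if not -1.0 <= self.gc_shift <= 1.0:
            raise ConfigurationError("gc_shift must lie in [-1, 1]")
        if not 0.0 <= self.homopolymer_noise <= 1.0:
            raise ConfigurationError("homopolymer_noise must lie in [0, 1]")

    @property
    def is_null(self) -> bool:
        return (self.gc_shift == 0.0 and self.dropout_slope == 0.0
                and self.homopolymer_noise == 0.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one generated sample pair."""

    n_groups: int = 4
    template_length: int = 250
    template_gc: tuple[float, ...] = (0.555, 0.55, 0.545, 0.54)
    inter_group_divergence: float = 0.02
    reads_per_group: int = 200
    mutation_rate: float = 0.01
    bias: BiasModel = field(default_factory=BiasModel)
    quality_phred: int = 38
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups <= 1:
            raise ConfigurationError("n_groups must be > 1")
        if len(self.template_gc) != self.n_groups:
            raise ConfigurationError("template_gc must list one target per group")
        for rate in (self.inter_group_divergence, self.mutation_rate, *self.template_gc):
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError("rates and GC fractions must lie in [0, 1]")
        if self.reads_per_group < 2:
            raise ConfigurationError("reads_per_group must be >= 2")


def _random_template(length: int, gc: float, rng: np.random.Generator) -> str:
    """Sequence whose GC count equals round(gc * length) exactly."""
    n_gc = round(gc * length)
    n_at = length - n_gc
    pool = (["G"] * ((n_gc + 1) // 2) + ["C"] * (n_gc // 2)
            + ["A"] * ((n_at + 1) // 2) + ["T"] * (n_at // 2))
    rng.shuffle(pool)
    return "".join(pool)


def _diverge(
    ancestor: str, divergence: float, gc_target: float, rng: np.random.Generator
) -> str:
    """Derive a template differing from the ancestor at exactly
    round(divergence * L) positions while hitting the GC target.

    The GC change is carried entirely by the divergent positions, so the
    target is reachable only when |target - ancestor| GC counts fit in
    the divergence budget.  Divergent positions are drawn uniformly,
    except that enough ancestor-G/C (or A/T) positions are guaranteed to
    make the target feasible.
    """
    L = len(ancestor)
    n_div = round(divergence * L)
    g0 = sum(c in "GC" for c in ancestor)
    target = round(gc_target * L)
    if abs(target - g0) > n_div:
        raise ConfigurationError(
            f"GC target {gc_target:.3f} unattainable at divergence {divergence:.3f}: "
            f"needs {abs(target - g0)} GC-class changes but only {n_div} "
            f"divergent positions are available"
        )
    gc_pool = np.array([i for i, c in enumerate(ancestor) if c in "GC"])
    at_pool = np.array([i for i, c in enumerate(ancestor) if c in "AT"])
    need_gc = max(0, g0 - target)   # ancestor-GC positions that must demote
    need_at = max(0, target - g0)   # ancestor-AT positions that must promote
    forced = np.concatenate([
        rng.choice(gc_pool, size=need_gc, replace=False) if need_gc else np.empty(0, int),
        rng.choice(at_pool, size=need_at, replace=False) if need_at else np.empty(0, int),
    ]).astype(int)
    remaining = np.setdiff1d(np.arange(L), forced)
    free = rng.choice(remaining, size=n_div - len(forced), replace=False)
    positions = np.concatenate([forced, free]).astype(int)
    # choose which divergent positions carry a G/C replacement so the
    # final count is exact: target = (g0 - a_gc) + x
    a_gc = sum(ancestor[i] in "GC" for i in positions)
    x = target - g0 + a_gc
    order = rng.permutation(positions)
    to_gc = set(int(i) for i in order[:x])
    t = list(ancestor)
    for i in positions:
        pool = "GC" if int(i) in to_gc else "AT"
        reps = [b for b in pool if b != ancestor[i]]
        t[i] = reps[rng.integers(len(reps))]
    return "".join(t)


def make_templates(
    config: SyntheticConfig, rng: Optional[np.random.Generator] = None
) -> list[str]:
    """Per-group templates: group 0 hits its GC target exactly; each
    further group diverges from group 0's template at the configured
    fraction of positions, then is GC-adjusted toward its own target."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    t0 = _random_template(config.template_length, config.template_gc[0], rng)
    templates = [t0]
    for gc in config.template_gc[1:]:
        templates.append(_diverge(t0, config.inter_group_divergence, gc, rng))
    return templates


# ---------------------------------------------------------------------------
# context-conditioned GC shift

_CONTEXT_FLANK = 2  # 5-mer contexts


def _shift_contexts(shift_at: bool) -> list[str]:
    centre = "AT" if shift_at else "GC"
    return ["".join(c) for c in itertools.product(
        BASES, BASES, centre, BASES, BASES)]


def make_shift_rule(
    templates: Sequence[str], gc_shift: float, rng: np.random.Generator
) -> dict[str, str]:
    """Per-sample miscall rule: context 5-mer -> replacement base.

    Contexts are shuffled once (independently of the shift magnitude, so
    rules for increasing |gc_shift| under the same seed are nested) and
    accumulated until the quota — |gc_shift| times the eligible-base
    count over the sample's templates — is met.
    """
    if gc_shift == 0.0:
        return {}
    shift_at = gc_shift > 0
    contexts = _shift_contexts(shift_at)
    # replacement for each context, drawn rule-wide before quota selection
    reps = "GC" if shift_at else "AT"
    replacements = {ctx: reps[rng.integers(2)] for ctx in contexts}
    order = list(contexts)
    rng.shuffle(order)
    counts: dict[str, int] = {}
    f = _CONTEXT_FLANK
    centre = "AT" if shift_at else "GC"
    for tpl in templates:
        for i in range(f, len(tpl) - f):
            if tpl[i] in centre:
                ctx = tpl[i - f:i + f + 1]
                counts[ctx] = counts.get(ctx, 0) + 1
    budget = abs(gc_shift) * sum(counts.values())
    rule: dict[str, str] = {}
    acc = 0
    for ctx in order:
        if acc >= budget:
            break
        if ctx in counts:
            rule[ctx] = replacements[ctx]
            acc += counts[ctx]
    return rule


def apply_shift_rule(template: str, rule: dict[str, str]) -> str:
    if not rule:
        return template
    f = _CONTEXT_FLANK
    t = list(template)
    for i in range(f, len(template) - f):
        rep = rule.get(template[i - f:i + f + 1])
        if rep is not None:
            t[i] = rep
    return "".join(t)


# ---------------------------------------------------------------------------
# per-read noise

def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    t = list(seq)
    hits = np.nonzero(rng.random(len(t)) < rate)[0]
    for i in hits:
        alts = [b for b in BASES if b != t[i]]
        t[i] = alts[rng.integers(3)]
    return "".join(t)


def _homopolymer_jitter(seq: str, prob: float, rng: np.random.Generator) -> str:
    """+/-1 length errors at homopolymer runs of length >= 3."""
    if prob <= 0.0:
        return seq
    out = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        run = seq[i:j]
        if len(run) >= 3 and rng.random() < prob:
            run = run + seq[i] if rng.random() < 0.5 else run[:-1]
        out.append(run)
        i = j
    return "".join(out)


def _retention_weight(gc: float, bias: BiasModel) -> float:
    if bias.dropout_slope == 0.0:
        return 1.0
    from scipy.special import expit
    w = float(expit(bias.dropout_slope * (gc - bias.dropout_midpoint)))
    return max(w, 1e-12)


def simulate_sample(
    templates: Sequence[str],
    config: SyntheticConfig,
    bias: BiasModel,
    sample_label: str,
    rng: Optional[np.random.Generator] = None,
    group_names: Optional[Sequence[str]] = None,
) -> SampleSet:
    """Generate reads_per_group truth-labelled reads from each template.

    Each read is its group's (bias-shifted) template with i.i.d.
    substitutions at ``mutation_rate``, optional homopolymer length
    jitter, and logistic GC dropout applied by rejection sampling.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if group_names is None:
        group_names = DEFAULT_GROUP_NAMES[:len(templates)]
    if len(group_names) != len(templates):
        raise ConfigurationError("one group name per template required")
    rule = make_shift_rule(templates, bias.gc_shift, rng)
    reads: list[ReadRecord] = []
    group_of: dict[str, str] = {}
    max_attempts = 200 * config.reads_per_group
    for gname, tpl in zip(group_names, templates):
        effective = apply_shift_rule(tpl, rule)
        accepted = 0
        attempts = 0
        while accepted < config.reads_per_group:
            attempts += 1
            if attempts > max_attempts:
                raise DegenerateInputError(
                    f"group {gname!r}: dropout too severe to collect "
                    f"{config.reads_per_group} reads"
                )
            seq = _mutate(effective, config.mutation_rate, rng)
            seq = _homopolymer_jitter(seq, bias.homopolymer_noise, rng)
            gc = (seq.count("G") + seq.count("C")) / len(seq)
            if rng.random() >= _retention_weight(gc, bias):
                continue
            rid = f"{sample_label}:{gname}:{accepted:04d}"
            reads.append(ReadRecord(
                rid, seq, [config.quality_phred] * len(seq)))
            group_of[rid] = gname
            accepted += 1
    return SampleSet(sample_label=sample_label, reads=reads, group_of=group_of)


def scenario(
    name: str,
    seed: int = 0,
    config: Optional[SyntheticConfig] = None,
    gc_shift: float = 0.08,
) -> tuple[SampleSet, SampleSet, str]:
    """Canonical two-sample experiments and their expected heatmap pattern.

    ``positive_control`` — two unbiased runs over identical templates;
    reads should cluster by phylogeny.  ``negative_control`` — the two
    samples read disjoint halves of double-length parent templates (the
    same groups, different amplified regions); reads should cluster by
    sample.  ``platform_bias`` — identical templates, GC-shift bias on
    sample B only; reads should cluster by sample.
    """
    if name not in SCENARIOS:
        raise ConfigurationError(
            f"unknown scenario {name!r}; valid names: {', '.join(SCENARIOS)}")
    cfg = config or SyntheticConfig()
    cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    no_bias = BiasModel()

    if name == "negative_control":
        parent_cfg = replace(cfg, template_length=2 * cfg.template_length)
        parents = make_templates(parent_cfg, rng)
        half = cfg.template_length
        templates_a = [p[:half] for p in parents]
        templates_b = [p[half:] for p in parents]
        a = simulate_sample(templates_a, cfg, no_bias, "A", rng)
        b = simulate_sample(templates_b, cfg, no_bias, "B", rng)
        return a, b, "sample_clustering"

    templates = make_templates(cfg, rng)
    a = simulate_sample(templates, cfg, no_bias, "A", rng)
    if name == "positive_control":
        b = simulate_sample(templates, cfg, no_bias, "B", rng)
        return a, b, "phylogenetic_clustering"
    # platform_bias
    b = simulate_sample(templates, cfg, BiasModel(gc_shift=gc_shift), "B", rng)
    expected = "phylogenetic_clustering" if gc_shift == 0.0 else "sample_clustering"
    return a, b, expected


def write_sample(sample: SampleSet, outdir: str | Path) -> tuple[Path, Path]:
    """Write one sample as FASTQ plus a read_id/group truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fastq = outdir / f"sample_{sample.sample_label}.fastq"
    truth = outdir / f"sample_{sample.sample_label}_groups.tsv"
    write_fastq(sample.reads, fastq)
    write_group_table(sample.group_of, truth)
    return fastq, truth
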