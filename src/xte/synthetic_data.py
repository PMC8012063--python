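"""Synthetic inputs with known ground truth.

Three generators cover every input the pipeline consumes:

* multi-tissue DE summary panels with planted, pathway-coherent effects
  — null genes carry Uniform(0,1] p-values and small zero-centered
  log2 fold-changes, signal genes in planted (set, tissue) cells carry
  Beta(a,1) p-values (a < 1) and signed fold-changes of subtle
  magnitude (default mean |log2FC| 0.07, i.e. ~5% change), and
  per-gene expression profiles are split across tissues by a Dirichlet
  draw whose concentration controls tissue specificity (small values
  produce near-point-mass profiles, mimicking hormone genes whose
  expression is >99% concentrated in one tissue);
* co-expression matrices with planted latent-factor module structure;
* cohorts with piecewise-constant status-specific hazards, optional
  status switches and administrative censoring.

All randomness flows from a single seed through named generators; the
same seed reproduces bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from xte.core_model import GeneSetCollection, TissuePanel
from xte.mortality import CohortTable

__all__ = [
    "PlantedEffect",
    "SimulationConfig",
    "GroundTruth",
    "simulate_de_summaries",
    "simulate_coexpression",
    "simulate_cohort",
    "DEFAULT_TISSUES",
]

#: Default tissue names for a 16-tissue panel.
DEFAULT_TISSUES = (
    "hippocampus", "hypothalamus", "pituitary", "thyroid", "heart", "muscle",
    "skin", "ileum", "colon", "spleen", "liver", "kidney", "adrenal",
    "testis", "ovary", "blood",
)


@dataclass
class PlantedEffect:
    """A pathway-coherent differential-expression effect.

    `beta_a` is the Beta(a, 1) shape for signal p-values (smaller =
    stronger signal); `direction_consistency` is the per-(gene, tissue)
    probability that the fold-change sign equals the planted direction;
    `fraction_affected` is the probability that a member gene carries
    the signal at all.  `tissues` = None plants the effect in every
    tissue.
    """

    name: str
    size: int = 20
    tissues: tuple[str, ...] | None = None
    direction: int = 1
    beta_a: float = 0.1
    mean_abs_log2fc: float = 0.07
    direction_consistency: float = 1.0
    fraction_affected: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        if not (0 < self.beta_a < 1):
            raise ValueError("beta_a must lie in (0, 1)")
        for prob in (self.direction_consistency, self.fraction_affected):
            if not (0 <= prob <= 1):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.size < 1:
            raise ValueError("set size must be positive")


@dataclass
class SimulationConfig:
    """Study conditions for the DE-summary generator.

    Defaults emulate the scale of a 16-tissue transcriptome screen:
    ~15,000 genes, 200 gene sets of 10–50 members, log-normal total
    expression split across tissues by a Dirichlet(0.1) profile (so a
    sizeable minority of genes are >99% expressed in one tissue), null
    fold-changes with SD 0.05.
    """

    n_genes: int = 15000
    n_tissues: int = 16
    n_sets: int = 200
    set_size_range: tuple[int, int] = (10, 50)
    planted: list[PlantedEffect] = field(default_factory=list)
    null_log2fc_sd: float = 0.05
    expr_log_mean: float = 4.0
    expr_log_sd: float = 1.5
    dirichlet_alpha: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_tissues, self.n_sets) <= 0:
            raise ValueError("counts must be positive")
        lo, hi = self.set_size_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid set size range")
        if self.dirichlet_alpha <= 0 or self.null_log2fc_sd < 0:
            raise ValueError("invalid distribution parameters")
        if len(self.planted) > self.n_sets:
            raise ValueError("more planted sets than total sets")

    def tissue_names(self) -> list[str]:
        if self.n_tissues == len(DEFAULT_TISSUES):
            return list(DEFAULT_TISSUES)
        return [f"T{i + 1:02d}" for i in range(self.n_tissues)]


@dataclass
class GroundTruth:
    """What was planted: per gene and per set."""

    is_signal: np.ndarray                  # (n_genes,) bool
    true_direction: np.ndarray             # (n_genes, n_tissues) int in {-1, 0, 1}
    planted_sets: dict[str, PlantedEffect]
    signal_genes: dict[str, list[str]]     # planted set -> affected member genes

    def planted_set_names(self) -> list[str]:
        return sorted(self.planted_sets)


def simulate_de_summaries(
    config: SimulationConfig,
) -> tuple[TissuePanel, GeneSetCollection, GroundTruth]:
    """Generate a DE-summary panel, a gene-set collection and the truth.

    Planted sets receive disjoint member-gene pools so ground truth is
    exact; the remaining sets draw members uniformly from all genes.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n_genes, n_tissues = config.n_genes, config.n_tissues
    genes = [f"G{i:05d}" for i in range(n_genes)]
    tissues = config.tissue_names()
    for eff in config.planted:
        if eff.tissues is not None and not set(eff.tissues).issubset(tissues):
            raise ValueError(f"planted effect {eff.name!r} names unknown tissues")

    total_planted_genes = sum(eff.size for eff in config.planted)
    if total_planted_genes > n_genes:
        raise ValueError(
            f"planted sets need {total_planted_genes} genes but only {n_genes} exist"
        )

    # Null layer for everything; planted cells overwritten below.
    p = 1.0 - rng.random((n_genes, n_tissues))          # Uniform(0, 1]
    log2fc = rng.normal(0.0, config.null_log2fc_sd, (n_genes, n_tissues))
    total_expr = rng.lognormal(config.expr_log_mean, config.expr_log_sd, n_genes)
    shares = rng.dirichlet(np.full(n_tissues, config.dirichlet_alpha), size=n_genes)
    mean_expr = total_expr[:, None] * shares

    # Member pools: planted sets are disjoint; null sets sample freely.
    pool = rng.permutation(n_genes)
    cursor = 0
    sets: dict[str, frozenset[str]] = {}
    is_signal = np.zeros(n_genes, dtype=bool)
    true_direction = np.zeros((n_genes, n_tissues), dtype=np.int8)
    planted_sets: dict[str, PlantedEffect] = {}
    signal_genes: dict[str, list[str]] = {}

    for eff in config.planted:
        members_idx = pool[cursor:cursor + eff.size]
        cursor += eff.size
        sets[eff.name] = frozenset(genes[i] for i in members_idx)
        planted_sets[eff.name] = eff
        t_idx = (
            np.arange(n_tissues)
            if eff.tissues is None
            else np.array([tissues.index(t) for t in eff.tissues])
        )
        affected = members_idx[rng.random(eff.size) < eff.fraction_affected]
        signal_genes[eff.name] = sorted(genes[i] for i in affected)
        is_signal[affected] = True
        for g in affected:
            p_sig = rng.beta(eff.beta_a, 1.0, t_idx.size)
            p[g, t_idx] = np.maximum(p_sig, np.finfo(float).tiny)
            signs = np.where(
                rng.random(t_idx.size) < eff.direction_consistency,
                eff.direction, -eff.direction,
            ).astype(np.int8)
            magnitude = rng.gamma(4.0, eff.mean_abs_log2fc / 4.0, t_idx.size)
            log2fc[g, t_idx] = signs * magnitude
            true_direction[g, t_idx] = signs

    lo, hi = config.set_size_range
    n_null_sets = config.n_sets - len(config.planted)
    for j in range(n_null_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(n_genes, size=size, replace=False)
        sets[f"NULL_SET_{j:04d}"] = frozenset(genes[i] for i in members)

    panel = TissuePanel(genes=genes, tissues=tissues, p=p, log2fc=log2fc,
                        mean_expr=mean_expr)
    collection = GeneSetCollection(sets=sets)
    truth = GroundTruth(is_signal=is_signal, true_direction=true_direction,
                        planted_sets=planted_sets, signal_genes=signal_genes)
    return panel, collection, truth


def simulate_coexpression(
    n_genes: int,
    n_samples: int,
    module_spec: list[tuple[int, float]],
    seed=None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Latent-factor co-expression matrix with planted modules.

    `module_spec` is a list of (module size, loading) pairs; genes in a
    module are loading * shared factor + sqrt(1 - loading^2) * noise,
    factors independent between modules.  Genes beyond the module
    budget are pure noise (label -1).

    Returns (expression genes x samples, module labels, gene names).
    """
    if n_samples < 3:
        raise ValueError("at least 3 samples are required for robust correlation")
    sizes = [s for s, _ in module_spec]
    loadings = [l for _, l in module_spec]
    if any(s <= 0 for s in sizes):
        raise ValueError("module sizes must be positive")
    if any(not (0 <= l <= 1) for l in loadings):
        raise ValueError("loadings must lie in [0, 1]")
    if sum(sizes) > n_genes:
        raise ValueError("modules request more genes than available")

    rng = np.random.default_rng(seed)
    labels = np.full(n_genes, -1, dtype=int)
    expr = rng.normal(0.0, 1.0, (n_genes, n_samples))
    row = 0
    for mod, (size, loading) in enumerate(module_spec):
        factor = rng.normal(0.0, 1.0, n_samples)
        block = loading * factor + np.sqrt(1.0 - loading**2) * expr[row:row + size]
        expr[row:row + size] = block
        labels[row:row + size] = mod
        row += size
    gene_names = [f"G{i:05d}" for i in range(n_genes)]
    return expr, labels, gene_names


def _piecewise_exponential_death(rng, segments) -> float:
    """Death age under piecewise-constant hazards.

    `segments`: list of (start_age, end_age_or_inf, hazard).  Inverts
    the cumulative hazard at a unit-exponential draw.
    """
    target = rng.exponential(1.0)
    used = 0.0
    for start, end, hazard in segments:
        span = end - start
        if np.isinf(span):
            return start + (target - used) / hazard
        step = hazard * span
        if used + step >= target:
            return start + (target - used) / hazard
        used += step
    raise AssertionError("segments must end with an open interval")


def simulate_cohort(
    n_individuals: int,
    hazard_by_status: dict[str, float],
    status_change_spec: dict | None = None,
    censor_spec: dict | float | None = None,
    seed=None,
) -> CohortTable:
    """Cohort with exponential lifetimes under status-specific hazards.

    `hazard_by_status` maps status to an annual hazard (> 0).
    `status_change_spec` (optional) is a dict with keys

    * ``initial``: mapping status -> proportion of individuals starting
      there (deterministic allocation; default: everyone starts in the
      alphabetically first status);
    * ``switches``: list of dicts with keys ``from``, ``to``, ``age``
      (a float or a (lo, hi) uniform range) and ``prob`` — applied in
      age order to individuals currently holding ``from``.

    `censor_spec` is an administrative censoring age (float, or dict
    with key ``age``); None means follow-up to death.
    """
    if n_individuals <= 0:
        raise ValueError("need at least one individual")
    if not hazard_by_status or any(h <= 0 for h in hazard_by_status.values()):
        raise ValueError("hazards must be positive")
    rng = np.random.default_rng(seed)
    spec = status_change_spec or {}
    statuses = sorted(hazard_by_status)
    initial = spec.get("initial") or {statuses[0]: 1.0}
    if not set(initial).issubset(statuses):
        raise ValueError("initial statuses must have hazards")
    switches = spec.get("switches", [])
    for sw in switches:
        if sw["from"] not in statuses or sw["to"] not in statuses:
            raise ValueError("switch references a status without a hazard")
    censor_age = None
    if censor_spec is not None:
        censor_age = censor_spec["age"] if isinstance(censor_spec, dict) else float(censor_spec)
        if censor_age <= 0:
            raise ValueError("censoring age must be positive")

    # Deterministic allocation of starting statuses by proportion.
    init_names = sorted(initial)
    props = np.array([initial[s] for s in init_names], dtype=float)
    props = props / props.sum()
    counts = np.floor(props * n_individuals).astype(int)
    counts[0] += n_individuals - counts.sum()
    start_status = np.repeat(init_names, counts)

    episode_rows, event_rows = [], []
    for i in range(n_individuals):
        ind = f"I{i:05d}"
        timeline = [(0.0, start_status[i])]
        current = start_status[i]
        for sw in switches:
            if sw["from"] != current:
                continue
            if rng.random() >= sw.get("prob", 1.0):
                continue
            age = sw["age"]
            if isinstance(age, (tuple, list)):
                age = rng.uniform(age[0], age[1])
            if age <= timeline[-1][0]:
                continue
            timeline.append((float(age), sw["to"]))
            current = sw["to"]

        segments = []
        for j, (start, status) in enumerate(timeline):
            end = timeline[j + 1][0] if j + 1 < len(timeline) else np.inf
            segments.append((start, end, hazard_by_status[status]))
        death_age = _piecewise_exponential_death(rng, segments)

        if censor_age is not None and censor_age < death_age:
            event, event_age = "censored", censor_age
        else:
            event, event_age = "death", death_age

        for j, (start, status) in enumerate(timeline):
            end = timeline[j + 1][0] if j + 1 < len(timeline) else event_age
            end = min(end, event_age)
            if end <= start:
                continue
            episode_rows.append((ind, status, start, end))
        event_rows.append((ind, event, event_age))

    episodes = pd.DataFrame(episode_rows, columns=["id", "status", "start", "end"])
    events = pd.DataFrame(event_rows, columns=["id", "event", "event_age"])
    return CohortTable(episodes=episodes, events=events)
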