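"""Core domain types, file I/O and shared statistics.

The central container is :class:`TissuePanel`: per-gene, per-tissue
differential-expression summaries (p-value, log2 fold-change for the
condition-of-interest vs. control contrast, and normalized mean
expression).  Gene sets are plain named collections of gene symbols read
from GMT files.  Shared statistics are Benjamini–Hochberg FDR, catalog
intersection, within-group sample-correlation QC and the all-zero gene
filter on raw counts.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: p-values of exactly 0 (as emitted by some DE tools) are clamped to this
#: before any logarithm is taken.
P_CLAMP = 1e-300

#: Scope token for cross-tissue (as opposed to single-tissue) results.
CROSS = "CROSS"

DE_TABLE_COLUMNS = ("gene", "pvalue", "log2fc", "base_mean")


class FormatError(ValueError):
    """Raised when an input file does not match its documented format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class TissuePanel:
    """Per-gene, per-tissue DE summaries for one contrast.

    Matrices are genes x tissues; missing (gene, tissue) entries are NaN
    and are never imputed — downstream statistics skip them.
    """

    genes: list[str]
    tissues: list[str]
    p: np.ndarray
    log2fc: np.ndarray
    mean_expr: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.log2fc = np.asarray(self.log2fc, dtype=float)
        self.mean_expr = np.asarray(self.mean_expr, dtype=float)
        shape = (len(self.genes), len(self.tissues))
        for name, mat in (("p", self.p), ("log2fc", self.log2fc),
                          ("mean_expr", self.mean_expr)):
            if mat.shape != shape:
                raise ValueError(f"{name} has shape {mat.shape}, expected {shape}")
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise ValueError(f"duplicate gene symbols: {dupes}")
        with np.errstate(invalid="ignore"):
            if np.any((self.p <= 0) | (self.p > 1)):
                raise ValueError("p-values must lie in (0, 1] where present")
            if np.any(self.mean_expr < 0):
                raise ValueError("mean expression must be nonnegative")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_tissues(self) -> int:
        return len(self.tissues)

    def tissue_index(self, tissue: str) -> int:
        try:
            return self.tissues.index(tissue)
        except ValueError:
            raise KeyError(f"unknown tissue {tissue!r}; have {self.tissues}") from None

    def gene_positions(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}


@dataclass
class GeneSetCollection:
    """Named sets of gene symbols (pathways, hallmarks, target lists)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            if any(not isinstance(g, str) or not g for g in members):
                raise ValueError(f"gene set {name!r} contains invalid symbols")
            self.sets[name] = frozenset(members)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


@dataclass
class EnrichmentResult:
    """One (gene set, scope) enrichment outcome.

    `scope` is a tissue name or the token ``CROSS``; `statistic_kind` is
    "F" (Fisher combination, -2*sum(ln p)) or "L" (sum |log2FC|).
    `direction_ratio` is F_up/F_down over set members split by
    fold-change sign; `direction_flag` records degenerate splits.
    """

    set_name: str
    scope: str
    statistic_kind: str
    statistic: float
    empirical_p: float
    fdr: float
    direction_ratio: float
    direction_flag: str
    n_draws_used: int
    m_effective: int

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError("statistic must be nonnegative")
        if not (0 < self.empirical_p <= 1):
            raise ValueError("empirical p must lie in (0, 1]")
        if self.empirical_p < 1.0 / (self.n_draws_used + 1) - 1e-12:
            raise ValueError("empirical p below the resolution of the draws used")


@dataclass
class CountMatrix:
    """Raw read counts (genes x samples) with complete sample metadata."""

    genes: list[str]
    samples: list[str]
    counts: np.ndarray
    metadata: pd.DataFrame  # columns: sample, species, sex, status, tissue

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError("counts shape does not match genes x samples")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)) or np.any(self.counts < 0):
                raise ValueError("counts must be nonnegative integers")
            self.counts = self.counts.astype(np.int64)
        required = {"sample", "species", "sex", "status", "tissue"}
        missing_cols = required - set(self.metadata.columns)
        if missing_cols:
            raise ValueError(f"sample metadata missing columns: {sorted(missing_cols)}")
        if set(self.metadata["sample"]) != set(self.samples):
            raise ValueError("metadata does not cover exactly the samples in the matrix")
        if self.metadata[sorted(required)].isna().any().any():
            raise ValueError("sample metadata must be complete for every sample")


@dataclass
class TableReadReport:
    """Ingest report for one DE table."""

    n_rows: int
    n_accepted: int
    n_rejected: int
    rejected_genes: list[str]
    n_clamped: int


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_de_table(path, tissue: str) -> tuple[TissuePanel, TableReadReport]:
    """Read a single-tissue DE summary table (TSV with header
    ``gene  pvalue  log2fc  base_mean``) into a one-tissue panel.

    Rows with non-numeric or out-of-range p are rejected and counted in
    the report; p of exactly 0 is clamped to ``P_CLAMP`` and logged.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene": str})
    missing = [c for c in DE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    df["gene"] = df["gene"].str.strip()
    dupes = df["gene"][df["gene"].duplicated()].unique().tolist()
    if dupes:
        raise FormatError(f"{path}: duplicate gene symbols {sorted(dupes)}")

    p = pd.to_numeric(df["pvalue"], errors="coerce")
    fc = pd.to_numeric(df["log2fc"], errors="coerce")
    expr = pd.to_numeric(df["base_mean"], errors="coerce")

    # NaN p is legitimate missingness (e.g. independent-filtering casualties)
    # and is carried through; out-of-range or non-numeric-with-content rows
    # are rejected.
    nonnumeric = p.isna() & df["pvalue"].notna() & (df["pvalue"].astype(str).str.strip() != "")
    out_of_range = p.notna() & ((p < 0) | (p > 1))
    bad_expr = expr.notna() & (expr < 0)
    reject = nonnumeric | out_of_range | bad_expr
    rejected_genes = df.loc[reject, "gene"].tolist()
    if reject.any():
        logger.warning("%s: rejected %d row(s): %s", path, int(reject.sum()),
                       rejected_genes)

    keep = ~reject
    p = p[keep].to_numpy()
    n_clamped = int(np.sum(p == 0))
    if n_clamped:
        logger.info("%s: clamped %d p-value(s) of exactly 0 to %g", path,
                    n_clamped, P_CLAMP)
    p = np.where(p == 0, P_CLAMP, p)

    panel = TissuePanel(
        genes=df.loc[keep, "gene"].tolist(),
        tissues=[tissue],
        p=p.reshape(-1, 1),
        log2fc=fc[keep].to_numpy().reshape(-1, 1),
        mean_expr=expr[keep].to_numpy().reshape(-1, 1),
    )
    report = TableReadReport(
        n_rows=len(df),
        n_accepted=int(keep.sum()),
        n_rejected=int(reject.sum()),
        rejected_genes=rejected_genes,
        n_clamped=n_clamped,
    )
    return panel, report


def write_de_table(panel: TissuePanel, path, tissue: str | None = None,
                   provenance: str | None = None) -> None:
    """Write one tissue of a panel back to the TSV contract."""
    t = panel.tissue_index(tissue) if tissue is not None else 0
    df = pd.DataFrame({
        "gene": panel.genes,
        "pvalue": panel.p[:, t],
        "log2fc": panel.log2fc[:, t],
        "base_mean": panel.mean_expr[:, t],
    })
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df.to_csv(fh, sep="\t", index=False)


def merge_tissue_panels(panels: list[TissuePanel]) -> TissuePanel:
    """Merge single/multi-tissue panels on the union of genes.

    Entries absent from a contributing panel are NaN (explicit missing).
    """
    if not panels:
        raise ValueError("no panels to merge")
    tissues: list[str] = []
    for pan in panels:
        for t in pan.tissues:
            if t in tissues:
                raise ValueError(f"tissue {t!r} appears in more than one panel")
            tissues.append(t)
    genes = sorted(set().union(*(pan.genes for pan in panels)))
    pos = {g: i for i, g in enumerate(genes)}
    shape = (len(genes), len(tissues))
    p = np.full(shape, np.nan)
    fc = np.full(shape, np.nan)
    expr = np.full(shape, np.nan)
    col = 0
    for pan in panels:
        rows = [pos[g] for g in pan.genes]
        ncol = pan.n_tissues
        p[rows, col:col + ncol] = pan.p
        fc[rows, col:col + ncol] = pan.log2fc
        expr[rows, col:col + ncol] = pan.mean_expr
        col += ncol
    return TissuePanel(genes=genes, tissues=tissues, p=p, log2fc=fc, mean_expr=expr)


def read_gmt(path) -> GeneSetCollection:
    """Read a standard GMT file: name, description, tab-separated members.

    Duplicate members within a set are deduplicated; empty sets are
    dropped with a warning.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name, desc = fields[0].strip(), fields[1]
            members = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not members:
                logger.warning("%s:%d: dropping empty set %r", path, lineno, name)
                continue
            sets[name] = members
            descriptions[name] = desc
    if not sets:
        logger.warning("%s: no gene sets read", path)
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.sets:
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def read_count_matrix(counts_path, metadata_path) -> CountMatrix:
    """Read a genes x samples count TSV plus a sample metadata TSV."""
    df = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
    meta = pd.read_csv(metadata_path, sep="\t", comment="#")
    return CountMatrix(
        genes=[str(g).strip() for g in df.index],
        samples=[str(s) for s in df.columns],
        counts=df.to_numpy(),
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# Shared statistics
# ---------------------------------------------------------------------------


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the order of the input."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-values are not allowed in bh_fdr")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def intersect_catalogs(symbols_a, symbols_b) -> list[str]:
    """Sorted, deduplicated intersection of two gene-symbol catalogs.

    Symbols are compared case-sensitively after whitespace stripping.
    """
    a = {s.strip() for s in symbols_a}
    b = {s.strip() for s in symbols_b}
    inter = sorted(a & b)
    logger.info(
        "catalog intersection: |A|=%d |B|=%d |union|=%d |intersection|=%d",
        len(a), len(b), len(a | b), len(inter),
    )
    return inter


def qc_sample_correlation(counts: CountMatrix, threshold: float = 0.90) -> pd.DataFrame:
    """Within-group pairwise Pearson QC on log2-transformed read counts.

    Groups are samples equal in (tissue, species, sex, status).  A sample
    fails if any within-group pairwise r on log2(count+1) drops below
    `threshold`; singleton groups are flagged untestable.

    Returns a per-sample DataFrame: sample, group, testable, min_r, pass.
    """
    log_counts = np.log2(counts.counts.astype(float) + 1.0)
    meta = counts.metadata.set_index("sample").loc[counts.samples]
    groups = meta.groupby(["tissue", "species", "sex", "status"]).groups
    col_of = {s: i for i, s in enumerate(counts.samples)}
    rows = []
    for key, members in groups.items():
        members = list(members)
        group_label = "/".join(str(k) for k in key)
        if len(members) < 2:
            rows.append((members[0], group_label, False, np.nan, True))
            continue
        cols = [col_of[s] for s in members]
        sub = log_counts[:, cols]
        r = np.corrcoef(sub.T)
        np.fill_diagonal(r, 1.0)
        min_r = np.min(r + np.eye(len(cols)) * 2, axis=1)  # min over partners
        for s, mr in zip(members, min_r):
            rows.append((s, group_label, True, float(mr), bool(mr >= threshold)))
    out = pd.DataFrame(rows, columns=["sample", "group", "testable", "min_r", "pass"])
    return out.set_index("sample").loc[counts.samples].reset_index()


def zero_filter(counts: CountMatrix) -> tuple[CountMatrix, int]:
    """Remove genes whose read count is zero across all samples."""
    keep = counts.counts.sum(axis=1) > 0
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("zero_filter: removed %d all-zero gene(s)", n_removed)
    filtered = CountMatrix(
        genes=[g for g, k in zip(counts.genes, keep) if k],
        samples=counts.samples,
        counts=counts.counts[keep],
        metadata=counts.metadata,
    )
    return filtered, n_removed


def provenance_header(seed=None, config: dict | None = None) -> str:
    """One-line provenance string for output tables."""
    from xte import __version__

    cfg_hash = "-"
    if config is not None:
        blob = repr(sorted(config.items())).encode()
        cfg_hash = hashlib.sha256(blob).hexdigest()[:12]
    return f"xte {__version__}, seed={seed}, config_hash={cfg_hash}"
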