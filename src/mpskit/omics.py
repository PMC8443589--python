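"""Transcriptomic scoring and calibration utilities.

Top-N gene ranking, directional concordance against signed marker sets,
one-sided Fisher's-exact enrichment with Bonferroni correction, cluster
comparison across conditions, per-row z-score matrices, a stand-in Welch
differential-expression test (gene-level calls use Benjamini-Hochberg FDR;
set-level calls use Bonferroni), and a plate/batch error-rate simulator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mpskit.errors import InputError

log = logging.getLogger(__name__)

DEG_COLUMNS = ("gene", "log2fc", "p", "fdr")


@dataclass
class MarkerSet:
    """Named reference gene set with expected directions.

    ``members`` maps gene -> expected direction in {-1, 0, +1}; 0 means the
    direction is unspecified.
    """

    name: str
    members: dict[str, int]

    def __post_init__(self) -> None:
        if not self.members:
            raise InputError("marker set must be non-empty")
        bad = {g: d for g, d in self.members.items() if d not in (-1, 0, 1)}
        if bad:
            raise InputError(f"directions must be in {{-1, 0, +1}}: {bad}")


@dataclass
class ConcordanceResult:
    set_name: str
    n_ref: int
    n_measured: int
    n_de: int
    n_directional: int
    pct_overlap: float | None
    pct_directional: float | None
    undefined: bool = False   # no reference gene present in the table


@dataclass
class EnrichmentRow:
    term: str
    k: int          # overlap of list and set
    K: int          # set size within the universe
    n: int          # list size
    N: int          # universe size
    p: float        # one-sided (greater) Fisher's exact
    p_adj: float    # Bonferroni over the sets tested in this call
    gene_ratio: float


@dataclass
class ZScoreMatrix:
    z: pd.DataFrame
    mask: pd.DataFrame                      # True where the cell is usable
    degenerate_rows: list[str] = field(default_factory=list)  # zero-variance rows
    masked_rows: list[str] = field(default_factory=list)      # <2 usable values


@dataclass
class BatchSimResult:
    n_genes: int
    reps_per_gene: int
    error_rates: np.ndarray        # per-gene error rate over resampled repeats
    median_error_rate_pct: float
    mean_error_rate_pct: float


def _validate_deg_table(table: pd.DataFrame) -> None:
    missing = [c for c in DEG_COLUMNS[:3] if c not in table.columns]
    if missing:
        raise InputError(f"DEG table missing columns: {missing}")
    if table["gene"].duplicated().any():
        raise InputError("DEG table genes must be unique")


def rank_top_genes(table: pd.DataFrame, n: int = 300, by: str = "p") -> list[str]:
    """Top-``n`` genes ranked by p ascending, ties broken by abs(log2fc)
    descending then gene id; ``by="log2fc"`` ranks by abs(log2fc) first
    (expression-magnitude reading) instead.

    The ordering is a total order, hence stable under input permutation.
    """
    _validate_deg_table(table)
    if table.empty:
        raise InputError("DEG table is empty")
    df = table.assign(_abs_lfc=table["log2fc"].abs())
    if by == "p":
        df = df.sort_values(["p", "_abs_lfc", "gene"], ascending=[True, False, True])
    elif by == "log2fc":
        df = df.sort_values(["_abs_lfc", "p", "gene"], ascending=[False, True, True])
    else:
        raise InputError(f"unknown ranking {by!r}")
    return df["gene"].head(n).tolist()


def concordance(
    table: pd.DataFrame, ref: MarkerSet, alpha: float = 0.05
) -> ConcordanceResult:
    """Directional concordance of a DEG table with a signed reference set.

    n_measured: reference genes present in the table; n_de: of those, genes
    with fdr < alpha; n_directional: DE genes whose log2fc sign matches the
    expected direction (direction-0 members count once DE regardless of
    sign).  Percentages use n_measured as denominator; a reference with no
    measured gene yields flagged undefined percentages, not an exception.
    """
    if not (0 < alpha < 1):
        raise InputError("alpha must lie in (0, 1)")
    _validate_deg_table(table)
    if "fdr" not in table.columns:
        raise InputError("DEG table missing 'fdr' column")
    idx = table.set_index("gene")
    measured = [g for g in ref.members if g in idx.index]
    n_de = 0
    n_dir = 0
    for g in measured:
        row = idx.loc[g]
        if row["fdr"] < alpha:
            n_de += 1
            expected = ref.members[g]
            if expected == 0 or np.sign(row["log2fc"]) == expected:
                n_dir += 1
    n_measured = len(measured)
    if n_measured == 0:
        return ConcordanceResult(
            set_name=ref.name,
            n_ref=len(ref.members),
            n_measured=0,
            n_de=0,
            n_directional=0,
            pct_overlap=None,
            pct_directional=None,
            undefined=True,
        )
    return ConcordanceResult(
        set_name=ref.name,
        n_ref=len(ref.members),
        n_measured=n_measured,
        n_de=n_de,
        n_directional=n_dir,
        pct_overlap=100.0 * n_de / n_measured,
        pct_directional=100.0 * n_dir / n_measured,
    )


def enrich(
    gene_list: list[str],
    collection: dict[str, set[str] | list[str] | dict[str, int]],
    universe: set[str] | list[str],
) -> list[EnrichmentRow]:
    """Over-representation of ``gene_list`` in each set of ``collection``.

    One-sided (greater) Fisher's exact p from the 2x2 table
    (k, n-k, K-k, N-K-n+k), equivalently the hypergeometric tail P(X >= k);
    Bonferroni multiplier = number of sets tested.  Rows sorted by p.
    """
    universe = set(universe)
    if not universe:
        raise InputError("universe is empty")
    query = set(gene_list)
    outside = query - universe
    if outside:
        log.warning("dropping %d query genes outside the universe", len(outside))
        query &= universe
    n = len(query)
    N = len(universe)
    m = len(collection)
    rows: list[EnrichmentRow] = []
    for term, members in collection.items():
        gene_set = set(members) & universe
        K = len(gene_set)
        k = len(query & gene_set)
        # hypergeometric upper tail: P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if n > 0 else 1.0
        rows.append(
            EnrichmentRow(
                term=term,
                k=k,
                K=K,
                n=n,
                N=N,
                p=min(p, 1.0),
                p_adj=min(1.0, m * min(p, 1.0)),
                gene_ratio=k / n if n else 0.0,
            )
        )
    rows.sort(key=lambda r: (r.p, r.term))
    return rows


def compare_clusters(
    lists: dict[str, list[str]],
    collection: dict[str, set[str] | list[str] | dict[str, int]],
    universe: set[str] | list[str],
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Per-condition enrichment, keeping rows with adjusted p < ``p_cut``.

    Conditions with no surviving term are absent from the output entirely.
    Columns: condition, term, k, K, n, N, gene_ratio, p, p_adj.
    """
    if not lists:
        raise InputError("at least one condition is required")
    records = []
    for condition, genes in lists.items():
        for row in enrich(genes, collection, universe):
            if row.p_adj < p_cut:
                records.append(
                    {
                        "condition": condition,
                        "term": row.term,
                        "k": row.k,
                        "K": row.K,
                        "n": row.n,
                        "N": row.N,
                        "gene_ratio": row.gene_ratio,
                        "p": row.p,
                        "p_adj": row.p_adj,
                    }
                )
    return pd.DataFrame(
        records, columns=["condition", "term", "k", "K", "n", "N", "gene_ratio", "p", "p_adj"]
    )


def zscore_matrix(values: pd.DataFrame, mask: pd.DataFrame | None = None) -> ZScoreMatrix:
    """Per-row standardisation: z = (x - row mean) / row sample sd (ddof 1).

    Statistics are computed over unmasked cells only; masked cells stay
    masked.  Rows with fewer than two usable values are fully masked; rows
    with zero variance become zeros and are flagged degenerate.
    """
    if mask is None:
        mask = pd.DataFrame(True, index=values.index, columns=values.columns)
    if not mask.index.equals(values.index) or not mask.columns.equals(values.columns):
        raise InputError("mask must align with values")
    z = pd.DataFrame(np.nan, index=values.index, columns=values.columns, dtype=float)
    out_mask = mask.copy()
    degenerate: list[str] = []
    masked_rows: list[str] = []
    for row in values.index:
        use = mask.loc[row].to_numpy(dtype=bool)
        x = values.loc[row].to_numpy(dtype=float)
        if use.sum() < 2:
            out_mask.loc[row] = False
            masked_rows.append(row)
            continue
        mu = x[use].mean()
        sd = x[use].std(ddof=1)
        if sd == 0:
            z.loc[row, use] = 0.0
            degenerate.append(row)
        else:
            z.loc[row, use] = (x[use] - mu) / sd
    return ZScoreMatrix(z=z, mask=out_mask, degenerate_rows=degenerate, masked_rows=masked_rows)


def _welch(
    a: np.ndarray, b: np.ndarray, axis: int = -1, var_floor: float = 1e-12
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Welch t-test with a variance floor for degenerate genes."""
    na, nb = a.shape[axis], b.shape[axis]
    ma, mb = a.mean(axis=axis), b.mean(axis=axis)
    va = np.maximum(a.var(axis=axis, ddof=1), var_floor)
    vb = np.maximum(b.var(axis=axis, ddof=1), var_floor)
    se2 = va / na + vb / nb
    t = (ma - mb) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p


def _student(
    a: np.ndarray, b: np.ndarray, axis: int = -1, var_floor: float = 1e-12
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised pooled-variance Student t-test (exact under an
    equal-variance normal null, unlike Welch at tiny n)."""
    na, nb = a.shape[axis], b.shape[axis]
    ma, mb = a.mean(axis=axis), b.mean(axis=axis)
    va = a.var(axis=axis, ddof=1)
    vb = b.var(axis=axis, ddof=1)
    df = na + nb - 2
    sp2 = np.maximum(((na - 1) * va + (nb - 1) * vb) / df, var_floor)
    t = (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p


def simple_de(
    matrix: pd.DataFrame, groups: dict[str, str] | list[str], alpha_fdr: float = 0.05
) -> pd.DataFrame:
    """Stand-in two-group differential test for synthetic log2-scale data.

    Per-gene Welch t-test between the two groups (a variance floor guards
    degenerate genes), Benjamini-Hochberg FDR, log2fc = group mean
    difference (non-reference minus first-listed group).  Returns a DEG
    table with columns gene, log2fc, p, fdr, significant.
    """
    if isinstance(groups, list):
        groups = dict(zip(matrix.columns, groups))
    labels = [groups[c] for c in matrix.columns]
    uniq = list(dict.fromkeys(labels))
    if len(uniq) != 2:
        raise InputError(f"exactly two groups required, got {uniq}")
    ref, other = uniq
    a_cols = [c for c in matrix.columns if groups[c] == other]
    b_cols = [c for c in matrix.columns if groups[c] == ref]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise InputError("each group needs >= 2 samples")
    a = matrix[a_cols].to_numpy(dtype=float)
    b = matrix[b_cols].to_numpy(dtype=float)
    _, p = _welch(a, b, axis=1)
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            "gene": matrix.index,
            "log2fc": a.mean(axis=1) - b.mean(axis=1),
            "p": p,
            "fdr": fdr,
            "significant": fdr < alpha_fdr,
        }
    ).reset_index(drop=True)


def simulate_batch_error(
    n_genes: int = 10000,
    reps: int = 3,
    batch_sd: float = 0.0,
    residual_sd: float = 1.0,
    design: str = "balanced",
    alpha: float = 0.05,
    n_repeats: int = 20,
    test: str = "student",
    seed: int = 0,
) -> BatchSimResult:
    """Null-model miscall-rate simulation under plate/batch structure.

    For every gene and resampled repeat, two groups of ``reps`` replicates
    are drawn with no true effect: residual noise plus plate offsets.  With
    ``design="balanced"`` each sample sits on its own plate (batch noise is
    exchangeable); with ``design="confounded"`` each group shares one plate,
    so plate offsets masquerade as group effects.  A gene is miscalled when
    its test rejects at ``alpha``; the test is configurable ("student",
    exactly nominal under this equal-variance null, or "welch").  Per-gene
    error rates are averaged over repeats; the headline number is their
    median across genes.
    """
    if batch_sd < 0 or residual_sd < 0:
        raise InputError("batch_sd and residual_sd must be >= 0")
    if design not in ("balanced", "confounded"):
        raise InputError(f"unknown design {design!r}")
    if test not in ("student", "welch"):
        raise InputError(f"unknown test {test!r}")
    rng = np.random.default_rng(seed)
    shape = (n_genes, n_repeats, 2, reps)
    data = rng.normal(0.0, residual_sd, size=shape) if residual_sd > 0 else np.zeros(shape)
    if batch_sd > 0:
        if design == "confounded":
            offsets = rng.normal(0.0, batch_sd, size=(n_genes, n_repeats, 2, 1))
        else:
            offsets = rng.normal(0.0, batch_sd, size=shape)
        data = data + offsets

    if residual_sd == 0 and batch_sd == 0:
        errors = np.zeros((n_genes, n_repeats), dtype=bool)
    else:
        testfn = _student if test == "student" else _welch
        _, p = testfn(data[:, :, 0, :], data[:, :, 1, :], axis=-1)
        errors = p < alpha
    rates = errors.mean(axis=1)
    return BatchSimResult(
        n_genes=n_genes,
        reps_per_gene=reps,
        error_rates=rates,
        median_error_rate_pct=100.0 * float(np.median(rates)),
        mean_error_rate_pct=100.0 * float(rates.mean()),
    )
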