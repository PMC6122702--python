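"""GEO2R-equivalent two-group differential expression per dataset.

The engine mirrors what NCBI's GEO2R front-end runs by default: an
empirical-Bayes moderated t-test.  Per-probe sample variances s_g^2 are
shrunk towards a prior variance s0^2 estimated from all probes, via the
posterior

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d),     d = nA + nB - 2,

and the moderated statistic t = logFC / (s_tilde * sqrt(1/nA + 1/nB)) is
referred to a t distribution with d0 + d degrees of freedom.  The prior
(d0, s0^2) is a method-of-moments fit of a scaled F distribution to the
observed variances, done on the log scale (the classical scheme).  With
d0 = 0 the statistic reduces to the ordinary pooled two-sample t; with
d0 -> infinity every probe is tested against the common prior variance.

Probe-level results are collapsed to one row per gene symbol (best-P probe)
before any cross-dataset step.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionDataset, normalize_symbol

__all__ = [
    "ShrinkageParams",
    "DiffExprTable",
    "estimate_shrinkage",
    "moderated_t_test",
    "collapse_probes",
    "bh_adjust",
    "diffexpr_table",
    "read_geo2r_table",
    "write_diffexpr_table",
    "read_diffexpr_table",
]

logger = logging.getLogger(__name__)

#: Column order of a collapsed per-gene table.
TABLE_COLUMNS = ["symbol", "logFC", "t", "p", "adj_p", "n_probes", "ambiguous"]


@dataclass(frozen=True)
class ShrinkageParams:
    """Empirical-Bayes prior for the variance: d0 prior df, s0_sq prior
    variance.  d0 may be ``inf`` (all variances shrunk to s0_sq); d0 = 0
    disables moderation."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("d0 must be >= 0")
        if not (self.s0_sq > 0) or math.isinf(self.s0_sq):
            raise ValueError("s0_sq must be finite and > 0")


@dataclass
class DiffExprTable:
    """Per-gene contrast statistics for one dataset.

    ``contrast`` is an ordered pair (A, B); logFC = mean(A) - mean(B) on the
    log2 scale, so a positive logFC means higher expression in group A.
    ``rows`` has columns symbol, logFC, t, p, adj_p, n_probes, ambiguous —
    one row per symbol; rows flagged ambiguous (significant probes that
    disagree in logFC sign) are excluded from downstream consensus.
    """

    dataset_id: str
    contrast: tuple[str, str]
    rows: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TABLE_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValueError(f"DiffExprTable missing columns {missing}")
        if self.rows["symbol"].duplicated().any():
            dup = self.rows["symbol"][self.rows["symbol"].duplicated()].iloc[0]
            raise ValueError(f"duplicate symbol {dup!r} in DiffExprTable")
        p = self.rows["p"].to_numpy()
        if ((p < 0) | (p > 1)).any():
            raise ValueError("p values outside [0, 1]")

    def usable(self) -> pd.DataFrame:
        """Rows eligible for consensus (non-ambiguous)."""
        return self.rows[~self.rows["ambiguous"]]

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.usable()[self.usable()["p"] < alpha]


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += step
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def estimate_shrinkage(sample_variances, d: float) -> ShrinkageParams:
    """Method-of-moments fit of the variance prior from per-probe variances.

    Under the hierarchical model, s^2 = s0^2 * F(d, d0) up to scale, so on
    the log scale  E[log s^2] and Var[log s^2] identify (d0, s0^2) through
    digamma/trigamma moments.  Requires >= 10 probes.  If the observed spread
    of log variances does not exceed what d alone explains, the fit returns
    d0 = inf; all-equal variances give (inf, that variance) exactly.
    """
    s2 = np.asarray(sample_variances, dtype=float)
    s2 = s2[np.isfinite(s2)]
    if s2.size < 10:
        raise ValueError(f"need >= 10 probes to estimate shrinkage, got {s2.size}")
    if d <= 0:
        raise ValueError("residual df d must be > 0")
    if (s2 < 0).any():
        raise ValueError("negative sample variances")
    if np.allclose(s2, s2[0]):
        return ShrinkageParams(d0=math.inf, s0_sq=float(s2[0]))
    positive = s2[s2 > 0]
    if positive.size < 10 or np.allclose(positive, positive[0]):
        logger.warning("degenerate variance distribution; falling back to d0=0")
        return ShrinkageParams(d0=0.0, s0_sq=float(max(s2.mean(), np.finfo(float).tiny)))
    z = np.log(positive)
    # moments of log F(d, d0): mean digamma(d/2)-log(d/2) - (digamma(d0/2)-log(d0/2)),
    # variance trigamma(d/2) + trigamma(d0/2)
    e_adj = z - special.digamma(d / 2.0) + math.log(d / 2.0)
    evar = float(np.var(e_adj, ddof=1)) - float(special.polygamma(1, d / 2.0))
    if evar <= 0:
        return ShrinkageParams(d0=math.inf, s0_sq=float(np.exp(e_adj.mean())))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(e_adj.mean() + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)))
    if not np.isfinite(s0_sq) or s0_sq <= 0:
        logger.warning("shrinkage estimation failed; falling back to d0=0")
        return ShrinkageParams(d0=0.0, s0_sq=float(positive.mean()))
    return ShrinkageParams(d0=float(d0), s0_sq=s0_sq)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _t_pvalue(t: np.ndarray, df) -> np.ndarray:
    """Two-sided P from a t (or, at infinite df, normal) distribution."""
    df = np.broadcast_to(np.asarray(df, dtype=float), t.shape)
    p = np.empty_like(t, dtype=float)
    fin = np.isfinite(df)
    p[fin] = 2.0 * stats.t.sf(np.abs(t[fin]), df[fin])
    p[~fin] = 2.0 * stats.norm.sf(np.abs(t[~fin]))
    return np.clip(p, 0.0, 1.0)


def moderated_t_test(dataset: ExpressionDataset, contrast: tuple[str, str],
                     shrinkage: ShrinkageParams | str = "estimate",
                     *, statistic: str = "moderated") -> pd.DataFrame:
    """Per-probe moderated (or Welch) t statistics for A vs B.

    logFC = mean(A) - mean(B).  Probes with fewer than two finite values in
    either group are dropped (count logged).  ``shrinkage`` is either fixed
    :class:`ShrinkageParams` or ``"estimate"`` to fit them from the data;
    ``statistic="welch"`` bypasses moderation entirely.

    Returns a DataFrame indexed by probe id with columns logFC, t, p, adj_p,
    s2, df_residual, df_total.
    """
    a_label, b_label = contrast
    a_samples = dataset.samples_in_group(a_label)
    b_samples = dataset.samples_in_group(b_label)
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValueError(
            f"{dataset.dataset_id}: each contrast group needs >=2 samples "
            f"(got {len(a_samples)} {a_label!r}, {len(b_samples)} {b_label!r})")
    if statistic not in ("moderated", "welch"):
        raise ValueError(f"statistic must be moderated|welch, got {statistic!r}")

    A = dataset.values[a_samples].to_numpy(dtype=float)
    B = dataset.values[b_samples].to_numpy(dtype=float)
    na = np.isfinite(A).sum(axis=1)
    nb = np.isfinite(B).sum(axis=1)
    usable = (na >= 2) & (nb >= 2)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("%s: dropped %d probe(s) with <2 finite values per group",
                    dataset.dataset_id, n_dropped)
    if not usable.any():
        raise ValueError(f"{dataset.dataset_id}: no usable probes")

    A, B = A[usable], B[usable]
    na, nb = na[usable].astype(float), nb[usable].astype(float)
    probes = dataset.values.index[usable]
    mean_a = np.nanmean(A, axis=1)
    mean_b = np.nanmean(B, axis=1)
    # ddof=1 sample variances; groups guaranteed >=2 finite values
    var_a = np.nanvar(A, axis=1, ddof=1)
    var_b = np.nanvar(B, axis=1, ddof=1)
    logfc = mean_a - mean_b

    if statistic == "welch":
        se2 = var_a / na + var_b / nb
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se2 > 0, logfc / np.sqrt(se2),
                         np.where(logfc == 0, 0.0, np.sign(logfc) * np.inf))
            df_num = se2 ** 2
            df_den = (var_a / na) ** 2 / (na - 1) + (var_b / nb) ** 2 / (nb - 1)
            df_total = np.where(df_den > 0, df_num / df_den, na + nb - 2)
        s2 = var_a / 2 + var_b / 2
        df_res = na + nb - 2
    else:
        df_res = na + nb - 2
        s2 = ((na - 1) * var_a + (nb - 1) * var_b) / df_res
        if shrinkage == "estimate":
            params = estimate_shrinkage(s2, d=float(np.median(df_res)))
        elif isinstance(shrinkage, ShrinkageParams):
            params = shrinkage
        else:
            raise ValueError("shrinkage must be ShrinkageParams or 'estimate'")
        if math.isinf(params.d0):
            s2_post = np.full_like(s2, params.s0_sq)
            df_total = np.full_like(s2, np.inf)
        else:
            s2_post = (params.d0 * params.s0_sq + df_res * s2) / (params.d0 + df_res)
            df_total = params.d0 + df_res
        se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, logfc / se,
                         np.where(logfc == 0, 0.0, np.sign(logfc) * np.inf))
    p = _t_pvalue(t, df_total)
    out = pd.DataFrame({
        "logFC": logfc, "t": t, "p": p, "adj_p": bh_adjust(p),
        "s2": s2, "df_residual": df_res, "df_total": df_total,
    }, index=pd.Index(probes, name="probe_id"))
    return out


def collapse_probes(probe_table: pd.DataFrame,
                    probe_to_gene: dict[str, str],
                    *, alpha_ambiguous: float = 0.05) -> pd.DataFrame:
    """Collapse per-probe statistics to one row per gene symbol.

    Probes with an empty symbol are dropped.  Per symbol the row with the
    smallest P is kept (ties: larger \\|logFC\\|, then lexicographically
    smallest probe id).  Genes whose significant probes (p < 0.05) disagree
    in logFC sign are flagged ``ambiguous`` so downstream consensus skips
    them.  ``n_probes`` records how many probes were collapsed per gene.
    """
    if "p" not in probe_table.columns:
        raise ValueError("probe table must have a p column")
    tbl = probe_table.copy()
    tbl["symbol"] = [normalize_symbol(probe_to_gene.get(str(pr), ""))
                     for pr in tbl.index]
    tbl = tbl[tbl["symbol"] != ""]
    if tbl.empty:
        return pd.DataFrame(columns=TABLE_COLUMNS)
    tbl = tbl.reset_index()
    probe_col = tbl.columns[0]  # original index name
    tbl["_abs_lfc"] = tbl["logFC"].abs()
    tbl = tbl.sort_values(["symbol", "p", "_abs_lfc", probe_col],
                          ascending=[True, True, False, True], kind="mergesort")
    n_probes = tbl.groupby("symbol", sort=True).size()
    sig = tbl[tbl["p"] < alpha_ambiguous]
    sign_counts = sig.groupby("symbol")["logFC"].agg(
        lambda v: (np.sign(v) > 0).any() and (np.sign(v) < 0).any())
    ambiguous = set(sign_counts[sign_counts].index)
    best = tbl.drop_duplicates("symbol", keep="first").set_index("symbol")
    out = pd.DataFrame({
        "symbol": best.index,
        "logFC": best["logFC"].to_numpy(),
        "t": best["t"].to_numpy(),
        "p": best["p"].to_numpy(),
        "adj_p": best["adj_p"].to_numpy() if "adj_p" in best else bh_adjust(best["p"]),
        "n_probes": n_probes.reindex(best.index).to_numpy(),
        "ambiguous": [s in ambiguous for s in best.index],
    }).reset_index(drop=True)
    return out


def diffexpr_table(dataset: ExpressionDataset, contrast: tuple[str, str],
                   shrinkage: ShrinkageParams | str = "estimate",
                   *, statistic: str = "moderated") -> DiffExprTable:
    """Run the per-probe test and collapse to a per-gene :class:`DiffExprTable`."""
    probe_stats = moderated_t_test(dataset, contrast, shrinkage,
                                   statistic=statistic)
    rows = collapse_probes(probe_stats, dataset.probe_to_gene)
    return DiffExprTable(dataset_id=dataset.dataset_id, contrast=contrast,
                         rows=rows)


# ---------------------------------------------------------------------------
# External table dialects
# ---------------------------------------------------------------------------

_GEO2R_COLUMNS = {
    "ID": "probe_id", "adj.P.Val": "adj_p", "P.Value": "p", "t": "t",
    "logFC": "logFC", "Gene.symbol": "symbol",
}


def read_geo2r_table(path, dataset_id: str,
                     contrast: tuple[str, str]) -> DiffExprTable:
    """Read a GEO2R-export TSV (ID, adj.P.Val, P.Value, t, logFC, Gene.symbol)
    and collapse it to a per-gene table; dialect detected from the header."""
    raw = pd.read_csv(path, sep="\t")
    missing = [c for c in _GEO2R_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: not a GEO2R export, missing columns {missing}")
    tbl = raw.rename(columns=_GEO2R_COLUMNS)
    tbl["symbol"] = tbl["symbol"].fillna("")
    tbl = tbl.set_index("probe_id")
    probe_to_gene = {str(p): s for p, s in tbl["symbol"].items()}
    rows = collapse_probes(tbl.drop(columns=["symbol"]), probe_to_gene)
    return DiffExprTable(dataset_id=dataset_id, contrast=contrast, rows=rows)


def write_diffexpr_table(table: DiffExprTable, path) -> None:
    from .io_formats import write_tsv
    out = table.rows[TABLE_COLUMNS].copy()
    out.insert(0, "dataset_id", table.dataset_id)
    out.insert(1, "contrast", f"{table.contrast[0]}_vs_{table.contrast[1]}")
    write_tsv(out, path)


def read_diffexpr_table(path) -> DiffExprTable:
    raw = pd.read_csv(path, sep="\t")
    dataset_id = str(raw["dataset_id"].iloc[0])
    a, _, b = raw["contrast"].iloc[0].partition("_vs_")
    rows = raw[TABLE_COLUMNS].copy()
    return DiffExprTable(dataset_id=dataset_id, contrast=(a, b), rows=rows)
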