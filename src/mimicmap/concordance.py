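"""Cross-dataset consensus selection and concordance/mimicry inference.

This is the analytical heart of the pipeline: genes consistently up- or
downregulated across cell-line datasets are selected (k-of-n consensus at a
nominal significance level, with genes qualifying in both directions
excluded), ranked against tumour datasets through the z-score of their log2
fold change, classified as concordant or discordant between the in-vitro and
tumour settings, and — for curated metabolic gene lists — attributed to the
cell line (HLE or HUH7) whose relative expression reproduces the tumour
pattern, based on the sign of the HLE - HUH7 difference in two independent
datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffexpr import DiffExprTable
from .io_formats import HMGList, normalize_symbol

__all__ = [
    "ConsensusGeneSet",
    "ConcordanceCall",
    "MimicryAssignment",
    "consensus_select",
    "consensus_pair",
    "top_core_genes",
    "zscore_fold",
    "average_z_rank",
    "classify_concordance",
    "assign_hmg_mimicry",
    "aggregate_by_process",
    "calls_to_frame",
    "assignments_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass
class ConsensusGeneSet:
    """Genes significant with a consistent direction in >= k_min datasets.

    ``members`` maps each gene to the ids of the datasets supporting it.
    Exclusivity holds by construction: a gene meeting the criterion in both
    directions (via different datasets) belongs to neither set.
    """

    direction: str  # "up" | "down"
    k_min: int
    alpha: float
    members: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be up|down, got {self.direction!r}")
        short = {g: s for g, s in self.members.items() if len(s) < self.k_min}
        if short:
            g = next(iter(short))
            raise ValueError(f"gene {g!r} has {len(short[g])} supporters < k_min")

    @property
    def genes(self) -> set[str]:
        return set(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return normalize_symbol(gene) in self.members

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "symbol": sorted(self.members),
            "direction": self.direction,
            "n_supporting": [len(self.members[g]) for g in sorted(self.members)],
            "supporting_datasets": [",".join(sorted(self.members[g]))
                                    for g in sorted(self.members)],
        })


@dataclass(frozen=True)
class ConcordanceCall:
    """Direction agreement of one consensus gene between cell lines and
    tumours.  concordant: same direction; discordant: opposite; unclassified:
    no (or tied) significant tumour evidence."""

    gene: str
    cellline_direction: str       # up | down
    tumour_direction: str         # up | down | none
    call: str                     # concordant | discordant | unclassified

    def __post_init__(self) -> None:
        expected = ("unclassified" if self.tumour_direction == "none"
                    else "concordant" if self.tumour_direction == self.cellline_direction
                    else "discordant")
        if self.call != expected:
            raise ValueError(
                f"{self.gene}: call {self.call!r} inconsistent with directions")


@dataclass(frozen=True)
class MimicryAssignment:
    """Attribution of one curated metabolic gene to HLE or HUH7.

    ``delta_sign_by_dataset`` holds the sign of (HLE - HUH7) per dataset.
    HLE mimics the tumour pattern when the signs agree across both datasets
    and match the list direction (up -> +, down -> -); agreement opposing the
    list direction points to HUH7; anything else is ambiguous.
    """

    gene: str
    hmg_direction: str                       # up | down
    delta_sign_by_dataset: tuple[tuple[str, str], ...]  # ((dataset_id, "+"|"-"|"0"), ...)
    assigned_to: str                         # HLE | HUH7 | ambiguous
    protein_support: str = "absent"          # agrees | disagrees | absent


def _per_table_direction_sets(tables: Sequence[DiffExprTable], alpha: float):
    """For each table: sets of genes significantly up / down (non-ambiguous)."""
    per = []
    for t in tables:
        sig = t.significant(alpha)
        up = set(sig.loc[sig["logFC"] > 0, "symbol"])
        down = set(sig.loc[sig["logFC"] < 0, "symbol"])
        per.append((t.dataset_id, up, down))
    return per


def consensus_pair(tables: Sequence[DiffExprTable], k_min: int = 2,
                   alpha: float = 0.05):
    """Build both consensus sets at once, enforcing exclusivity.

    Returns ``(up_set, down_set, excluded)`` where ``excluded`` is the set of
    genes qualifying in both directions (dropped from both, logged).
    """
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    if k_min > len(tables):
        raise ValueError(
            f"k_min={k_min} exceeds the number of datasets ({len(tables)})")
    per = _per_table_direction_sets(tables, alpha)
    up_support: dict[str, set[str]] = {}
    down_support: dict[str, set[str]] = {}
    for dataset_id, up, down in per:
        for g in up:
            up_support.setdefault(g, set()).add(dataset_id)
        for g in down:
            down_support.setdefault(g, set()).add(dataset_id)
    up_genes = {g for g, s in up_support.items() if len(s) >= k_min}
    down_genes = {g for g, s in down_support.items() if len(s) >= k_min}
    excluded = up_genes & down_genes
    if excluded:
        logger.info("consensus: %d gene(s) qualified in both directions and "
                    "were excluded: %s", len(excluded),
                    ",".join(sorted(excluded)[:10]))
    up = ConsensusGeneSet("up", k_min, alpha,
                          {g: frozenset(up_support[g])
                           for g in up_genes - excluded})
    down = ConsensusGeneSet("down", k_min, alpha,
                            {g: frozenset(down_support[g])
                             for g in down_genes - excluded})
    return up, down, excluded


def consensus_select(tables: Sequence[DiffExprTable], direction: str,
                     k_min: int = 2, alpha: float = 0.05) -> ConsensusGeneSet:
    """Select genes significant (p < alpha) with the stated logFC sign in at
    least ``k_min`` datasets, excluding genes that also qualify in the
    opposite direction."""
    up, down, _ = consensus_pair(tables, k_min=k_min, alpha=alpha)
    return up if direction == "up" else down if direction == "down" else (
        (_ for _ in ()).throw(ValueError(f"direction must be up|down, got {direction!r}")))


def top_core_genes(tables: Sequence[DiffExprTable], direction: str,
                   n: int = 100, alpha_adj: float = 1e-4) -> list[str]:
    """Core genes: the intersection of each dataset's top-n list.

    Per table, the n genes with the stated logFC sign ranked by ascending
    adjusted P (ties: larger \\|logFC\\|, then symbol order).  The result is the
    intersection across all tables, restricted to adjusted P < alpha_adj in
    every table, ordered by mean within-list rank (ties by symbol).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be up|down, got {direction!r}")
    sign = 1 if direction == "up" else -1
    rank_maps: list[dict[str, int]] = []
    adj_maps: list[dict[str, float]] = []
    for t in tables:
        rows = t.usable()
        rows = rows[np.sign(rows["logFC"]) == sign].copy()
        rows["_abs"] = rows["logFC"].abs()
        rows = rows.sort_values(["adj_p", "_abs", "symbol"],
                                ascending=[True, False, True], kind="mergesort")
        top = rows.head(n)
        rank_maps.append({s: i for i, s in enumerate(top["symbol"], start=1)})
        adj_maps.append(dict(zip(rows["symbol"], rows["adj_p"])))
    core = set(rank_maps[0])
    for rm in rank_maps[1:]:
        core &= set(rm)
    core = {g for g in core if all(am[g] < alpha_adj for am in adj_maps)}
    return sorted(core, key=lambda g: (np.mean([rm[g] for rm in rank_maps]), g))


def zscore_fold(table: DiffExprTable, gene_subset: set[str] | None = None,
                *, alpha: float = 0.05) -> pd.Series:
    """z-score of the log2 fold change over a dataset's significant genes.

    z_g = (logFC_g - mean(logFC)) / sd(logFC) with the sample (n-1) standard
    deviation, computed over the dataset's significant genes (p < alpha),
    optionally restricted to ``gene_subset``.  All-equal logFC gives all
    zeros.  Fewer than 2 genes is an error.
    """
    rows = table.significant(alpha)
    if gene_subset is not None:
        subset = {normalize_symbol(g) for g in gene_subset}
        rows = rows[rows["symbol"].isin(subset)]
    if len(rows) < 2:
        raise ValueError(
            f"{table.dataset_id}: need >=2 genes with logFC to z-score, got {len(rows)}")
    lfc = rows["logFC"].to_numpy(dtype=float)
    sd = lfc.std(ddof=1)
    z = np.zeros_like(lfc) if sd == 0 else (lfc - lfc.mean()) / sd
    return pd.Series(z, index=pd.Index(rows["symbol"], name="symbol"), name=table.dataset_id)


def average_z_rank(profiles: Mapping[str, pd.Series],
                   genes: Sequence[str]) -> pd.DataFrame:
    """Average the per-dataset z-scores and rank genes by the mean.

    ``profiles`` maps tumour dataset id -> per-gene z Series (as produced by
    :func:`zscore_fold`).  The average is taken only over datasets where the
    gene is present; genes present nowhere get NaN and sort last.  The table
    is ordered by descending avg_z with ties broken by symbol, and ``rank``
    is a dense 1-based ordering.  Heatmap-ready: one z column per dataset.
    """
    if not profiles:
        raise ValueError("need >=1 dataset profile")
    genes = [normalize_symbol(g) for g in genes]
    data = {f"z_{ds}": series.reindex(genes).to_numpy()
            for ds, series in profiles.items()}
    out = pd.DataFrame({"symbol": genes, **data})
    zcols = [c for c in out.columns if c.startswith("z_")]
    out["avg_z"] = out[zcols].mean(axis=1, skipna=True)
    out = out.sort_values(["avg_z", "symbol"], ascending=[False, True],
                          kind="mergesort", na_position="last").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def _tumour_direction(gene: str, tumour_tables: Sequence[DiffExprTable],
                      alpha: float) -> str:
    """Majority logFC sign among tumour datasets where the gene is
    significant; exact tie or no significant dataset -> 'none'."""
    n_up = n_down = 0
    for t in tumour_tables:
        rows = t.significant(alpha)
        hit = rows[rows["symbol"] == gene]
        if hit.empty:
            continue
        lfc = float(hit["logFC"].iloc[0])
        if lfc > 0:
            n_up += 1
        elif lfc < 0:
            n_down += 1
    if n_up == n_down:
        return "none"
    return "up" if n_up > n_down else "down"


def classify_concordance(consensus: ConsensusGeneSet,
                         tumour_tables: Sequence[DiffExprTable],
                         *, alpha: float = 0.05) -> list[ConcordanceCall]:
    """Call each consensus gene concordant/discordant/unclassified against
    the tumour datasets (majority significant sign; ties -> unclassified)."""
    if not consensus.members:
        raise ValueError("consensus set is empty")
    # index significant rows once per table for speed
    sig_sign: list[dict[str, int]] = []
    for t in tumour_tables:
        rows = t.significant(alpha)
        sig_sign.append({s: int(np.sign(l))
                         for s, l in zip(rows["symbol"], rows["logFC"]) if l != 0})
    calls = []
    for gene in sorted(consensus.members):
        n_up = sum(1 for m in sig_sign if m.get(gene) == 1)
        n_down = sum(1 for m in sig_sign if m.get(gene) == -1)
        if n_up == n_down:
            tdir = "none"
        else:
            tdir = "up" if n_up > n_down else "down"
        call = ("unclassified" if tdir == "none"
                else "concordant" if tdir == consensus.direction
                else "discordant")
        calls.append(ConcordanceCall(gene=gene,
                                     cellline_direction=consensus.direction,
                                     tumour_direction=tdir, call=call))
    return calls


def calls_to_frame(calls: Sequence[ConcordanceCall]) -> pd.DataFrame:
    return pd.DataFrame({
        "symbol": [c.gene for c in calls],
        "cellline_direction": [c.cellline_direction for c in calls],
        "tumour_direction": [c.tumour_direction for c in calls],
        "call": [c.call for c in calls],
    })


def _sign_char(x: float) -> str:
    return "+" if x > 0 else "-" if x < 0 else "0"


def assign_hmg_mimicry(hmg_up: HMGList, hmg_down: HMGList,
                       deltas: Mapping[str, Mapping[str, float]],
                       protein_folds: Mapping[str, float] | None = None,
                       *, protein_veto: bool = False) -> list[MimicryAssignment]:
    """Attribute each curated metabolic gene to HLE or HUH7.

    ``deltas`` maps exactly two dataset ids to per-gene (HLE - HUH7)
    expression differences.  A gene present in both tables is assigned to HLE
    when the delta signs agree across datasets and match its list direction
    (up -> +, down -> -), to HUH7 when they agree and oppose it, and is
    ambiguous otherwise.  Genes absent from either table are excluded
    (logged).  ``protein_folds`` maps gene -> linear HLE/HUH7 protein fold;
    support is 'agrees' when sign(log fold) matches the transcript delta
    sign.  With ``protein_veto``, disagreement demotes the assignment to
    ambiguous.
    """
    if len(deltas) != 2:
        raise ValueError(f"need exactly 2 delta tables, got {len(deltas)}")
    if hmg_up.direction != "up" or hmg_down.direction != "down":
        raise ValueError("expected (up, down) HMG lists")
    ds_ids = sorted(deltas)
    tables = {ds: {normalize_symbol(g): float(v) for g, v in deltas[ds].items()}
              for ds in ds_ids}
    folds = ({normalize_symbol(g): float(v) for g, v in protein_folds.items()}
             if protein_folds is not None else {})
    assignments: list[MimicryAssignment] = []
    n_skipped = 0
    for direction, hmg in (("up", hmg_up), ("down", hmg_down)):
        for gene in sorted(hmg.genes):
            if any(gene not in tables[ds] for ds in ds_ids):
                n_skipped += 1
                continue
            signs = [np.sign(tables[ds][gene]) for ds in ds_ids]
            sign_map = tuple((ds, _sign_char(tables[ds][gene])) for ds in ds_ids)
            if signs[0] == signs[1] and signs[0] != 0:
                matches = (signs[0] > 0) == (direction == "up")
                assigned = "HLE" if matches else "HUH7"
                tx_sign = signs[0]
            else:
                assigned = "ambiguous"
                tx_sign = np.sign(sum(tables[ds][gene] for ds in ds_ids))
            if gene in folds and folds[gene] > 0 and tx_sign != 0:
                prot_sign = np.sign(np.log2(folds[gene]))
                support = ("agrees" if prot_sign == tx_sign
                           else "disagrees" if prot_sign != 0 else "absent")
            else:
                support = "absent"
            if protein_veto and support == "disagrees":
                assigned = "ambiguous"
            assignments.append(MimicryAssignment(
                gene=gene, hmg_direction=direction,
                delta_sign_by_dataset=sign_map,
                assigned_to=assigned, protein_support=support))
    if n_skipped:
        logger.info("mimicry: %d HMG(s) absent from at least one delta table "
                    "were excluded", n_skipped)
    return assignments


def assignments_to_frame(assignments: Sequence[MimicryAssignment]) -> pd.DataFrame:
    return pd.DataFrame({
        "symbol": [a.gene for a in assignments],
        "hmg_direction": [a.hmg_direction for a in assignments],
        "delta_signs": [";".join(f"{ds}:{s}" for ds, s in a.delta_sign_by_dataset)
                        for a in assignments],
        "assigned_to": [a.assigned_to for a in assignments],
        "protein_support": [a.protein_support for a in assignments],
    })


def aggregate_by_process(assignments: Sequence[MimicryAssignment],
                         process_map: Mapping[str, str]) -> pd.DataFrame:
    """Count assigned genes per (metabolic process, cell line, direction).

    Only genes assigned to HLE or HUH7 are counted; genes without a process
    entry fall under "Others".  Returns a tidy count table.
    """
    pmap = {normalize_symbol(g): str(p) for g, p in process_map.items()}
    counts: dict[tuple[str, str, str], int] = {}
    for a in assignments:
        if a.assigned_to not in ("HLE", "HUH7"):
            continue
        process = pmap.get(a.gene, "Others")
        key = (process, a.assigned_to, a.hmg_direction)
        counts[key] = counts.get(key, 0) + 1
    rows = sorted(counts)
    return pd.DataFrame({
        "process": [r[0] for r in rows],
        "cell_line": [r[1] for r in rows],
        "direction": [r[2] for r in rows],
        "count": [counts[r] for r in rows],
    })
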