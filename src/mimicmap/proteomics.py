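"""Proteomics overlay: significance filters, fold ranking, and gene-protein
agreement scoring.

The module consumes a summarized mass-spectrometry results table (one row per
protein: encoding gene symbol, unique-peptide count, linear mean fold
HLE/HUH7, FDR-adjusted ANOVA P).  Folds are stored linear (as reported) and
compared on the log2 scale where a sign is needed; the "fold difference > 2"
criterion is applied on the linear scale in either direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .concordance import MimicryAssignment
from .io_formats import ValidationError, normalize_symbol

__all__ = [
    "ProteomicsTable",
    "read_proteomics_table",
    "filter_significant_proteins",
    "top_fold_proteins",
    "gene_protein_agreement",
]

PROTEOMICS_COLUMNS = ["symbol", "unique_peptides", "mean_fold", "adj_p", "direction"]


@dataclass
class ProteomicsTable:
    """Summarized protein-level results, one row per protein.

    ``mean_fold`` is the linear HLE/HUH7 fold (> 0); ``direction`` is
    HLE_higher when the fold exceeds 1 and HUH7_higher when below.
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PROTEOMICS_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValidationError(f"proteomics table missing columns {missing}")
        r = self.rows
        if (r["unique_peptides"] < 0).any():
            raise ValidationError("unique_peptides must be >= 0")
        if (r["mean_fold"] <= 0).any():
            raise ValidationError("mean_fold must be > 0")
        expected = np.where(r["mean_fold"].to_numpy() >= 1.0,
                            "HLE_higher", "HUH7_higher")
        bad = r["direction"].to_numpy() != expected
        # a fold of exactly 1 may legitimately carry either label
        bad &= r["mean_fold"].to_numpy() != 1.0
        if bad.any():
            sym = r.loc[bad, "symbol"].iloc[0]
            raise ValidationError(
                f"{sym}: direction inconsistent with mean_fold")
        self.rows = r.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.rows)

    def fold_by_gene(self) -> dict[str, float]:
        return dict(zip(self.rows["symbol"], self.rows["mean_fold"]))


def read_proteomics_table(path) -> ProteomicsTable:
    """Read a TSV proteomics results table.

    Required columns (case-insensitive match on common spellings): gene
    symbol, unique-peptide count, mean fold (HLE/HUH7, linear), adjusted P.
    The direction column is derived from the fold when absent.
    """
    raw = pd.read_csv(path, sep="\t")
    colmap = {}
    for col in raw.columns:
        key = col.strip().lower().replace(" ", "_").replace(".", "_")
        if key in {"symbol", "gene", "gene_symbol", "protein"}:
            colmap[col] = "symbol"
        elif "peptide" in key:
            colmap[col] = "unique_peptides"
        elif "fold" in key:
            colmap[col] = "mean_fold"
        elif key in {"adj_p", "adj_p_val", "fdr", "adjusted_p", "padj", "q_value"}:
            colmap[col] = "adj_p"
        elif key == "direction":
            colmap[col] = "direction"
    tbl = raw.rename(columns=colmap)
    needed = ["symbol", "unique_peptides", "mean_fold", "adj_p"]
    missing = [c for c in needed if c not in tbl.columns]
    if missing:
        raise ValidationError(f"{path}: cannot locate column(s) {missing}")
    tbl = tbl[[c for c in PROTEOMICS_COLUMNS if c in tbl.columns]].copy()
    tbl["symbol"] = tbl["symbol"].map(normalize_symbol)
    tbl["unique_peptides"] = tbl["unique_peptides"].astype(int)
    tbl["mean_fold"] = tbl["mean_fold"].astype(float)
    if "direction" not in tbl.columns:
        tbl["direction"] = np.where(tbl["mean_fold"] >= 1.0,
                                    "HLE_higher", "HUH7_higher")
    return ProteomicsTable(rows=tbl[PROTEOMICS_COLUMNS])


def filter_significant_proteins(table: ProteomicsTable,
                                min_peptides: int = 2,
                                alpha: float = 0.05) -> ProteomicsTable:
    """Keep proteins with >= min_peptides unique peptides and adjusted
    P < alpha.  Idempotent."""
    r = table.rows
    keep = (r["unique_peptides"] >= min_peptides) & (r["adj_p"] < alpha)
    return ProteomicsTable(rows=r[keep].reset_index(drop=True))


def top_fold_proteins(table: ProteomicsTable, n: int = 20,
                      min_fold: float = 2.0):
    """The top-n most differential proteins per direction.

    HLE-higher rows need mean_fold > min_fold; HUH7-higher rows need
    1/mean_fold > min_fold.  Each list is ranked by descending effective
    fold (ties by symbol).  Returns ``(hle_higher, huh7_higher)`` frames.
    """
    r = table.rows.copy()
    hle = r[(r["direction"] == "HLE_higher") & (r["mean_fold"] > min_fold)].copy()
    hle["effective_fold"] = hle["mean_fold"]
    huh7 = r[(r["direction"] == "HUH7_higher") &
             (1.0 / r["mean_fold"] > min_fold)].copy()
    huh7["effective_fold"] = 1.0 / huh7["mean_fold"]
    out = []
    for part in (hle, huh7):
        part = part.sort_values(["effective_fold", "symbol"],
                                ascending=[False, True], kind="mergesort")
        out.append(part.head(n).reset_index(drop=True))
    return out[0], out[1]


def _transcript_sign(assignment: MimicryAssignment) -> int:
    signs = {s for _, s in assignment.delta_sign_by_dataset}
    if signs == {"+"}:
        return 1
    if signs == {"-"}:
        return -1
    return 0


def gene_protein_agreement(assignments: Sequence[MimicryAssignment],
                           table: ProteomicsTable):
    """Score per-gene sign agreement between transcript deltas and protein
    folds.

    A gene agrees when sign(log2 mean_fold) matches its consistent
    transcript (HLE - HUH7) delta sign; genes absent from the proteomics
    table are reported with status 'absent'.  Returns ``(frame, fraction)``
    where fraction is agreements / (agreements + disagreements).
    """
    folds = table.fold_by_gene()
    records = []
    n_agree = n_disagree = 0
    for a in assignments:
        tx = _transcript_sign(a)
        if a.gene not in folds or tx == 0:
            status = "absent"
        else:
            prot = int(np.sign(np.log2(folds[a.gene])))
            if prot == 0:
                status = "absent"
            elif prot == tx:
                status, n_agree = "agrees", n_agree + 1
            else:
                status, n_disagree = "disagrees", n_disagree + 1
        records.append((a.gene, a.hmg_direction, a.assigned_to,
                        folds.get(a.gene, np.nan), status))
    frame = pd.DataFrame(records, columns=[
        "symbol", "hmg_direction", "assigned_to", "mean_fold", "agreement"])
    total = n_agree + n_disagree
    fraction = n_agree / total if total else float("nan")
    return frame, fraction
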