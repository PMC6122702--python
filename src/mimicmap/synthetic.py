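"""Planted-truth simulator for the whole pipeline.

Generates the complete input bundle the pipeline consumes — cell-line and
tumour expression datasets, curated directional metabolic gene lists, a
gene-set collection with planted enriched terms, two cell-line (HLE - HUH7)
delta tables, a proteomics table correlated with the transcript deltas, and a
process map — together with the planted truth, so that every stage can be
scored for recovery without any download.

The expression model is additive on the log2 scale: per dataset, baseline
gene means are Normal(8, 2), planted differential genes are shifted by
+/- delta in the appropriate group, and per-sample noise is Normal(0, sigma).
Genes are expanded to 1-3 probes per platform and each gene is dropped from
each dataset independently with a platform-dropout probability, emulating
cross-platform coverage differences.  A fixed seed makes every draw — and
every written byte — reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (ExpressionDataset, GeneSet, GeneSetCollection,
                         HMGList, write_expression_dataset, write_gmt,
                         write_tsv)
from .proteomics import ProteomicsTable

__all__ = ["GeneratorConfig", "SyntheticTruth", "SyntheticBundle",
           "generate", "score_recovery", "run_planted_recovery",
           "PROCESS_NAMES"]

PROCESS_NAMES = (
    "glycolysis", "TCA cycle", "fatty acid metabolism", "urea cycle",
    "amino acid metabolism", "molecule transport", "cholesterol metabolism",
    "nucleotide metabolism",
)

DELTA_DATASET_IDS = ("DELTA_A", "DELTA_B")


@dataclass
class GeneratorConfig:
    """Knobs of the simulator; defaults are the study conditions.

    Three cell-line and four tumour contrasts mirror the real design;
    ``effect_size_log2`` of 3 noise SDs with 10 samples per group gives
    clearly separated planted effects; planted fractions of 8% up / 8% down
    and 85% concordance among planted genes match the scale of consensus
    signatures seen in liver-tumour meta-analyses.
    """

    n_genes: int = 2000
    n_celline_datasets: int = 3
    n_tumour_datasets: int = 4
    samples_per_group: int = 10
    effect_size_log2: float = 3.0
    noise_sd: float = 1.0
    fraction_up: float = 0.08
    fraction_down: float = 0.08
    fraction_concordant: float = 0.85
    probe_multiplicity_probs: tuple[float, float, float] = (0.7, 0.2, 0.1)
    platform_dropout_prob: float = 0.05
    n_gene_sets: int = 50
    gene_set_size: int = 25
    planted_enriched_terms: int = 1
    proteomics_noise_sd: float = 0.5
    n_background_proteins: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_up", "fraction_down", "fraction_concordant",
                     "platform_dropout_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.fraction_up + self.fraction_down > 1.0:
            raise ValueError("fraction_up + fraction_down must be <= 1")
        if self.effect_size_log2 < 0 or self.noise_sd <= 0:
            raise ValueError("effect_size_log2 must be >= 0 and noise_sd > 0")
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if self.samples_per_group < 2:
            raise ValueError("samples_per_group must be >= 2")
        if self.n_celline_datasets < 1 or self.n_tumour_datasets < 1:
            raise ValueError("need >= 1 dataset of each role")
        probs = self.probe_multiplicity_probs
        if len(probs) != 3 or any(p < 0 for p in probs) or not math.isclose(sum(probs), 1.0):
            raise ValueError("probe_multiplicity_probs must be 3 probabilities summing to 1")
        if self.planted_enriched_terms > self.n_gene_sets:
            raise ValueError("planted_enriched_terms exceeds n_gene_sets")
        if not (0 <= self.seed < 2**31):
            raise ValueError("seed must be in [0, 2^31)")


@dataclass
class SyntheticTruth:
    """Planted labels for recovery scoring.

    ``frame`` is indexed by gene symbol with columns: cellline_direction,
    tumour_direction, concordance, hmg, process, mimicry ('' where not
    applicable) and one boolean ``present_<dataset>`` column per dataset
    recording which planted effects survived dropout.  ``planted_terms``
    lists the term ids whose members were drawn from planted upregulated
    genes.
    """

    frame: pd.DataFrame
    planted_terms: list[str]
    config: GeneratorConfig
    instance_id: str

    def recoverable(self, direction: str, k_min: int = 2) -> set[str]:
        """Planted genes of one cell-line direction present in >= k_min
        cell-line datasets (the ceiling any k-of-n consensus can reach)."""
        f = self.frame
        cl_cols = [c for c in f.columns
                   if c.startswith("present_CL")]
        present = f[cl_cols].sum(axis=1)
        mask = (f["cellline_direction"] == direction) & (present >= k_min)
        return set(f.index[mask])


@dataclass
class SyntheticBundle:
    """Everything :func:`generate` emits, ready for the pipeline."""

    datasets: list[ExpressionDataset]
    hmg_up: HMGList
    hmg_down: HMGList
    gene_sets: GeneSetCollection
    proteomics: ProteomicsTable
    delta_tables: dict[str, dict[str, float]]
    process_map: dict[str, str]
    truth: SyntheticTruth

    def celline_datasets(self) -> list[ExpressionDataset]:
        return [d for d in self.datasets if d.dataset_id.startswith("CL")]

    def tumour_datasets(self) -> list[ExpressionDataset]:
        return [d for d in self.datasets if d.dataset_id.startswith("TU")]

    def write(self, outdir) -> dict[str, object]:
        """Write the full bundle in the formats io_formats reads; returns a
        manifest of relative paths (stable ordering, stable bytes)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest: dict[str, object] = {"datasets": []}
        for ds in self.datasets:
            paths = {
                "id": ds.dataset_id,
                "role": "cellline" if ds.dataset_id.startswith("CL") else "tumour",
                "matrix": f"{ds.dataset_id}_matrix.tsv",
                "groups": f"{ds.dataset_id}_groups.tsv",
                "annot": f"{ds.dataset_id}_annot.tsv",
                "contrast": (["poorly_diff", "well_diff"]
                             if ds.dataset_id.startswith("CL")
                             else ["tumour", "non_tumour"]),
            }
            write_expression_dataset(ds, outdir / paths["matrix"],
                                     outdir / paths["groups"],
                                     outdir / paths["annot"])
            manifest["datasets"].append(paths)
        for name, hmg in (("hmg_up.txt", self.hmg_up), ("hmg_down.txt", self.hmg_down)):
            (outdir / name).write_text("\n".join(sorted(hmg.genes)) + "\n")
            manifest[name.split(".")[0]] = name
        write_gmt(self.gene_sets, outdir / "gene_sets.gmt")
        manifest["gene_sets"] = "gene_sets.gmt"
        write_tsv(self.proteomics.rows, outdir / "proteomics.tsv")
        manifest["proteomics"] = "proteomics.tsv"
        for ds_id, deltas in self.delta_tables.items():
            frame = pd.DataFrame({"symbol": sorted(deltas),
                                  "delta": [deltas[g] for g in sorted(deltas)]})
            write_tsv(frame, outdir / f"delta_{ds_id}.tsv")
        manifest["delta_tables"] = [f"delta_{d}.tsv" for d in sorted(self.delta_tables)]
        pm = pd.DataFrame({"symbol": sorted(self.process_map),
                           "process": [self.process_map[g]
                                       for g in sorted(self.process_map)]})
        write_tsv(pm, outdir / "process_map.tsv")
        manifest["process_map"] = "process_map.tsv"
        truth = self.truth.frame.copy()
        truth.insert(0, "symbol", truth.index)
        write_tsv(truth, outdir / "truth.tsv")
        manifest["truth"] = "truth.tsv"
        manifest["instance_id"] = self.truth.instance_id
        return manifest


def _gene_names(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _simulate_dataset(rng: np.random.Generator, config: GeneratorConfig,
                      dataset_id: str, genes: Sequence[str],
                      shift: np.ndarray, group_a: str, group_b: str):
    """One expression dataset: returns (ExpressionDataset, present_mask).

    ``shift`` is the per-gene log2 shift applied to group A samples.
    """
    n = len(genes)
    present = rng.random(n) >= config.platform_dropout_prob
    baseline = rng.normal(8.0, 2.0, size=n)
    multiplicity = rng.choice([1, 2, 3], size=n,
                              p=config.probe_multiplicity_probs)
    spg = config.samples_per_group
    samples = ([f"{dataset_id}_{group_a}_{i+1}" for i in range(spg)]
               + [f"{dataset_id}_{group_b}_{i+1}" for i in range(spg)])
    groups = {s: (group_a if i < spg else group_b)
              for i, s in enumerate(samples)}
    probe_ids: list[str] = []
    probe_gene_idx: list[int] = []
    for gi in range(n):
        if not present[gi]:
            continue
        for rep in range(int(multiplicity[gi])):
            probe_ids.append(f"{genes[gi]}_p{rep+1}")
            probe_gene_idx.append(gi)
    idx = np.asarray(probe_gene_idx)
    mean_a = baseline[idx] + shift[idx]
    mean_b = baseline[idx]
    noise = rng.normal(0.0, config.noise_sd, size=(len(idx), 2 * spg))
    values = np.empty((len(idx), 2 * spg))
    values[:, :spg] = mean_a[:, None] + noise[:, :spg]
    values[:, spg:] = mean_b[:, None] + noise[:, spg:]
    frame = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                         columns=samples)
    probe_to_gene = {p: genes[g] for p, g in zip(probe_ids, idx)}
    dataset = ExpressionDataset(dataset_id=dataset_id, platform_id=f"SIM_{dataset_id}",
                                values=frame, probe_to_gene=probe_to_gene,
                                sample_groups=groups)
    return dataset, present


def generate(config: GeneratorConfig) -> SyntheticBundle:
    """Generate a full synthetic input bundle with planted truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = _gene_names(n)
    delta = config.effect_size_log2

    # --- planted differential structure -------------------------------
    n_up = int(round(config.fraction_up * n))
    n_down = int(round(config.fraction_down * n))
    planted_idx = rng.choice(n, size=n_up + n_down, replace=False)
    cellline_dir = np.array([""] * n, dtype=object)
    cellline_dir[planted_idx[:n_up]] = "up"
    cellline_dir[planted_idx[n_up:]] = "down"
    concordant = rng.random(n) < config.fraction_concordant
    tumour_dir = np.array([""] * n, dtype=object)
    for gi in planted_idx:
        if concordant[gi]:
            tumour_dir[gi] = cellline_dir[gi]
        else:
            tumour_dir[gi] = "down" if cellline_dir[gi] == "up" else "up"
    concordance = np.where(
        cellline_dir == "", "",
        np.where(np.asarray([concordant[i] for i in range(n)]),
                 "concordant", "discordant"))
    concordance = np.where(cellline_dir == "", "", concordance).astype(object)

    dir_sign = {"up": 1.0, "down": -1.0, "": 0.0}
    cl_shift = np.array([dir_sign[d] for d in cellline_dir]) * delta
    tu_shift = np.array([dir_sign[d] for d in tumour_dir]) * delta

    # --- expression datasets ------------------------------------------
    datasets: list[ExpressionDataset] = []
    present_cols: dict[str, np.ndarray] = {}
    for i in range(config.n_celline_datasets):
        ds_id = f"CL{i+1}"
        ds, present = _simulate_dataset(rng, config, ds_id, genes, cl_shift,
                                        "poorly_diff", "well_diff")
        datasets.append(ds)
        present_cols[f"present_{ds_id}"] = present
    for i in range(config.n_tumour_datasets):
        ds_id = f"TU{i+1}"
        ds, present = _simulate_dataset(rng, config, ds_id, genes, tu_shift,
                                        "tumour", "non_tumour")
        datasets.append(ds)
        present_cols[f"present_{ds_id}"] = present

    # --- curated metabolic lists (tumour-derived directions) ----------
    hmg_up_genes = [genes[i] for i in range(n) if tumour_dir[i] == "up"]
    hmg_down_genes = [genes[i] for i in range(n) if tumour_dir[i] == "down"]
    hmg_up = HMGList("up", frozenset(hmg_up_genes), source="synthetic")
    hmg_down = HMGList("down", frozenset(hmg_down_genes), source="synthetic")
    hmg = np.where(np.isin(genes, hmg_up_genes), "up",
                   np.where(np.isin(genes, hmg_down_genes), "down", "")).astype(object)

    # --- process map over the metabolic lists -------------------------
    hmg_all = sorted(hmg_up_genes + hmg_down_genes)
    process_map = {g: PROCESS_NAMES[int(k)] for g, k in
                   zip(hmg_all, rng.integers(0, len(PROCESS_NAMES), len(hmg_all)))}
    process = np.array([process_map.get(g, "") for g in genes], dtype=object)

    # --- gene sets with planted enrichment ----------------------------
    planted_up_genes = [genes[i] for i in range(n) if cellline_dir[i] == "up"]
    collection = GeneSetCollection()
    planted_terms: list[str] = []
    size = min(config.gene_set_size, n)
    for t in range(config.planted_enriched_terms):
        n_from_planted = min(int(round(0.8 * size)), len(planted_up_genes))
        members = list(rng.choice(planted_up_genes, n_from_planted, replace=False))
        others = [g for g in genes if g not in set(members)]
        members += list(rng.choice(others, size - n_from_planted, replace=False))
        term = f"PLANTED_{t+1}"
        collection.add(GeneSet(term, f"planted enriched set {t+1}", "pathway",
                               frozenset(members)))
        planted_terms.append(term)
    for t in range(config.n_gene_sets - config.planted_enriched_terms):
        members = rng.choice(genes, size, replace=False)
        collection.add(GeneSet(f"RAND_{t+1:03d}", f"random set {t+1}", "pathway",
                               frozenset(members)))

    # --- HLE - HUH7 delta tables and mimicry truth --------------------
    mimicry = np.array([""] * n, dtype=object)
    delta_tables: dict[str, dict[str, float]] = {d: {} for d in DELTA_DATASET_IDS}
    hmg_idx = [i for i in range(n) if hmg[i]]
    mimic_draw = rng.random(n) < 0.5
    for i in hmg_idx:
        mimicry[i] = "HLE" if mimic_draw[i] else "HUH7"
        sign = 1.0 if (hmg[i] == "up") == (mimicry[i] == "HLE") else -1.0
        for ds in DELTA_DATASET_IDS:
            delta_tables[ds][genes[i]] = float(
                sign * delta + rng.normal(0.0, config.noise_sd))

    # --- proteomics table correlated with transcript deltas -----------
    prot_genes = [genes[i] for i in hmg_idx]
    mean_delta = np.array([(delta_tables[DELTA_DATASET_IDS[0]][g]
                            + delta_tables[DELTA_DATASET_IDS[1]][g]) / 2.0
                           for g in prot_genes])
    log_fold = mean_delta + rng.normal(0.0, config.proteomics_noise_sd,
                                       len(prot_genes))
    non_hmg = [genes[i] for i in range(n) if not hmg[i]]
    n_bg = min(config.n_background_proteins, len(non_hmg))
    bg_genes = list(rng.choice(non_hmg, n_bg, replace=False))
    bg_fold = rng.normal(0.0, config.proteomics_noise_sd, n_bg)
    all_genes = prot_genes + bg_genes
    all_logf = np.concatenate([log_fold, bg_fold])
    peptides = 1 + rng.poisson(3.0, len(all_genes))
    adj_p = np.concatenate([rng.uniform(0.0, 0.04, len(prot_genes)),
                            rng.uniform(0.05, 1.0, n_bg)])
    mean_fold = np.power(2.0, all_logf)
    prot = pd.DataFrame({
        "symbol": all_genes,
        "unique_peptides": peptides.astype(int),
        "mean_fold": mean_fold,
        "adj_p": adj_p,
        "direction": np.where(mean_fold >= 1.0, "HLE_higher", "HUH7_higher"),
    }).sort_values("symbol", kind="mergesort").reset_index(drop=True)
    proteomics = ProteomicsTable(rows=prot)

    # --- truth ---------------------------------------------------------
    term_membership = []
    for g in genes:
        term_membership.append(",".join(t for t in planted_terms
                                        if g in collection.sets[t].genes))
    frame = pd.DataFrame({
        "cellline_direction": cellline_dir,
        "tumour_direction": tumour_dir,
        "concordance": concordance,
        "hmg": hmg,
        "process": process,
        "mimicry": mimicry,
        "planted_terms": term_membership,
        **{k: v for k, v in present_cols.items()},
    }, index=pd.Index(genes, name="symbol"))
    instance_id = f"sim-{config.seed}-{n}-{config.n_celline_datasets}x{config.n_tumour_datasets}"
    truth = SyntheticTruth(frame=frame, planted_terms=planted_terms,
                           config=config, instance_id=instance_id)
    return SyntheticBundle(datasets=datasets, hmg_up=hmg_up, hmg_down=hmg_down,
                           gene_sets=collection, proteomics=proteomics,
                           delta_tables=delta_tables, process_map=process_map,
                           truth=truth)


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

def _rate(num: int, den: int) -> float:
    return num / den if den else float("nan")


def score_recovery(truth: SyntheticTruth, *,
                   consensus_up=None, consensus_down=None,
                   calls=None, assignments=None,
                   enrichment_rows=None, k_min: int = 2) -> pd.DataFrame:
    """Sensitivity/specificity of pipeline outputs against the planted truth.

    For concordance calls, "concordant" is treated as the positive class
    among planted recoverable genes (specificity = fraction of planted
    discordant genes not called concordant); mimicry analogously with HLE
    as the positive class.  Outputs referring to genes unknown to the truth
    raise an error (mismatched instance).
    """
    f = truth.frame
    known = set(f.index)
    rows: list[tuple[str, float, int]] = []

    def check_known(genes_iter, what):
        stray = set(genes_iter) - known
        if stray:
            raise ValueError(
                f"{what} contains gene(s) not in this synthetic instance, "
                f"e.g. {sorted(stray)[0]!r}")

    if consensus_up is not None and consensus_down is not None:
        pred_up, pred_down = set(consensus_up.genes), set(consensus_down.genes)
        check_known(pred_up | pred_down, "consensus output")
        for direction, pred in (("up", pred_up), ("down", pred_down)):
            pos = truth.recoverable(direction, k_min)
            rows.append((f"consensus_{direction}_sensitivity",
                         _rate(len(pos & pred), len(pos)), len(pos)))
        neg = set(f.index[f["cellline_direction"] == ""])
        fp = len(neg & (pred_up | pred_down))
        rows.append(("consensus_specificity", _rate(len(neg) - fp, len(neg)), len(neg)))

    if calls is not None:
        call_map = {c.gene: c.call for c in calls}
        check_known(call_map, "concordance calls")
        evaluable = (truth.recoverable("up", k_min)
                     | truth.recoverable("down", k_min))
        t_con = {g for g in evaluable if f.loc[g, "concordance"] == "concordant"}
        t_dis = {g for g in evaluable if f.loc[g, "concordance"] == "discordant"}
        tp = sum(1 for g in t_con if call_map.get(g) == "concordant")
        tn = sum(1 for g in t_dis if call_map.get(g) != "concordant")
        dis_hit = sum(1 for g in t_dis if call_map.get(g) == "discordant")
        rows.append(("concordant_sensitivity", _rate(tp, len(t_con)), len(t_con)))
        rows.append(("discordant_sensitivity", _rate(dis_hit, len(t_dis)), len(t_dis)))
        rows.append(("concordance_specificity", _rate(tn, len(t_dis)), len(t_dis)))

    if assignments is not None:
        amap = {a.gene: a.assigned_to for a in assignments}
        check_known(amap, "mimicry assignments")
        t_hle = set(f.index[f["mimicry"] == "HLE"]) & set(amap)
        t_huh = set(f.index[f["mimicry"] == "HUH7"]) & set(amap)
        rows.append(("mimicry_sensitivity",
                     _rate(sum(1 for g in t_hle if amap[g] == "HLE"),
                           len(t_hle)), len(t_hle)))
        rows.append(("mimicry_specificity",
                     _rate(sum(1 for g in t_huh if amap[g] != "HLE"),
                           len(t_huh)), len(t_huh)))

    if enrichment_rows is not None and truth.planted_terms:
        pathways = enrichment_rows[enrichment_rows["category"] == "pathway"]
        order = list(pathways.sort_values(["p", "k", "term_id"],
                                          ascending=[True, False, True],
                                          kind="mergesort")["term_id"])
        rank = min((order.index(t) + 1 for t in truth.planted_terms
                    if t in order), default=float("nan"))
        rows.append(("planted_term_rank", float(rank), len(order)))

    return pd.DataFrame(rows, columns=["metric", "value", "n"])


def run_planted_recovery(config: GeneratorConfig, *, k_min: int = 2,
                         alpha: float = 0.05):
    """Generate a bundle, run the full analysis in memory, score recovery.

    This is the package's standing recovery experiment: differential
    expression per dataset, k-of-n consensus, concordance calls against the
    tumour datasets, mimicry attribution from the delta tables, and
    enrichment of the upregulated consensus set — all measured against the
    planted truth.  Returns ``(bundle, results, metrics)`` where ``results``
    holds the intermediate objects and ``metrics`` the scoring frame.
    """
    from .concordance import (assign_hmg_mimicry, classify_concordance,
                              consensus_pair)
    from .diffexpr import diffexpr_table
    from .enrichment import hypergeom_enrich

    bundle = generate(config)
    cell_tables = [diffexpr_table(ds, ("poorly_diff", "well_diff"))
                   for ds in bundle.celline_datasets()]
    tumour_tables = [diffexpr_table(ds, ("tumour", "non_tumour"))
                     for ds in bundle.tumour_datasets()]
    consensus_up, consensus_down, _ = consensus_pair(cell_tables, k_min=k_min,
                                                     alpha=alpha)
    calls = []
    for cs in (consensus_up, consensus_down):
        if cs.members:
            calls += classify_concordance(cs, tumour_tables, alpha=alpha)
    assignments = assign_hmg_mimicry(bundle.hmg_up, bundle.hmg_down,
                                     bundle.delta_tables)
    universe = set(cell_tables[0].rows["symbol"])
    for tb in cell_tables[1:]:
        universe &= set(tb.rows["symbol"])
    enrichment_rows = hypergeom_enrich(consensus_up.genes, bundle.gene_sets,
                                       universe, mode="ease")
    metrics = score_recovery(bundle.truth,
                             consensus_up=consensus_up,
                             consensus_down=consensus_down,
                             calls=calls, assignments=assignments,
                             enrichment_rows=enrichment_rows, k_min=k_min)
    results = {"cell_tables": cell_tables, "tumour_tables": tumour_tables,
               "consensus_up": consensus_up, "consensus_down": consensus_down,
               "calls": calls, "assignments": assignments,
               "enrichment": enrichment_rows}
    return bundle, results, metrics
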