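"""End-to-end orchestration with a YAML config and a reproducible report.

Stages run in order: diffexpr -> consensus -> zrank -> concordance ->
mimicry -> enrichment -> proteomics.  Every intermediate is written as TSV
under the output directory, together with a run manifest (config hash, seed,
package version, per-stage gene accounting) and a summary of the headline
counts.  Identical config + inputs + seed produce byte-identical output
bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from . import __version__
from .concordance import (assign_hmg_mimicry, assignments_to_frame,
                          aggregate_by_process, calls_to_frame,
                          classify_concordance, consensus_pair,
                          top_core_genes, zscore_fold, average_z_rank)
from .diffexpr import DiffExprTable, diffexpr_table, read_geo2r_table, \
    write_diffexpr_table
from .enrichment import hypergeom_enrich, select_top_terms
from .io_formats import (check_hmg_pair, normalize_symbol, read_expression_dataset,
                         read_gmt, read_hmg_list, write_tsv)
from .proteomics import (filter_significant_proteins, gene_protein_agreement,
                         read_proteomics_table, top_fold_proteins)

__all__ = ["PipelineConfig", "DatasetSpec", "validate_config", "run_pipeline",
           "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("diffexpr", "consensus", "zrank", "concordance", "mimicry",
          "enrichment", "proteomics")

_THRESHOLD_DEFAULTS = {
    "alpha": 0.05,       # per-dataset significance for consensus and z-ranking
    "k_min": 2,          # datasets required for consensus membership
    "alpha_adj": 1e-4,   # adjusted-P cut for the top core genes
    "top_n": 100,        # per-dataset top list size for core genes
    "p_max": 1e-4,       # enrichment P threshold
    "fdr_max": 0.25,     # enrichment FDR threshold
    "min_peptides": 2,   # proteomics unique-peptide filter
    "min_fold": 2.0,     # proteomics fold filter (linear, either direction)
    "top_proteins": 20,  # per-direction protein list size
}

_MODE_DEFAULTS = {
    "enrichment": "ease",        # ease | standard
    "statistic": "moderated",    # moderated | welch
    "protein_veto": False,       # let protein disagreement demote assignments
    "log2_transform": "auto",    # auto | on | off
}


@dataclass
class DatasetSpec:
    id: str
    role: str                      # cellline | tumour
    contrast: tuple[str, str]
    matrix: str | None = None
    groups: str | None = None
    annot: str | None = None
    geo2r: str | None = None       # precomputed GEO2R export instead of a matrix

    def __post_init__(self) -> None:
        if self.role not in ("cellline", "tumour"):
            raise ValueError(f"{self.id}: role must be cellline|tumour")
        if self.geo2r is None and (self.matrix is None or self.groups is None):
            raise ValueError(f"{self.id}: need matrix+groups or a geo2r table")


@dataclass
class PipelineConfig:
    datasets: list[DatasetSpec]
    outdir: str
    seed: int = 0
    hmg_up: str | None = None
    hmg_down: str | None = None
    gene_sets: str | None = None
    gene_sets_category: str = "pathway"
    proteomics: str | None = None
    delta_tables: dict[str, str] = dc_field(default_factory=dict)
    process_map: str | None = None
    thresholds: dict[str, float] = dc_field(default_factory=dict)
    modes: dict[str, Any] = dc_field(default_factory=dict)
    base_dir: Path = Path(".")

    def __post_init__(self) -> None:
        self.thresholds = {**_THRESHOLD_DEFAULTS, **self.thresholds}
        self.modes = {**_MODE_DEFAULTS, **self.modes}
        unknown = set(self.thresholds) - set(_THRESHOLD_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown threshold key(s): {sorted(unknown)}")
        unknown = set(self.modes) - set(_MODE_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown mode key(s): {sorted(unknown)}")
        t = self.thresholds
        if not (0 < t["alpha"] <= 1):
            raise ValueError(f"alpha must be in (0, 1], got {t['alpha']}")
        if not (0 < t["p_max"] <= 1) or not (0 < t["fdr_max"] <= 1):
            raise ValueError("p_max and fdr_max must be in (0, 1]")
        if not (0 < t["alpha_adj"] <= 1):
            raise ValueError(f"alpha_adj must be in (0, 1], got {t['alpha_adj']}")
        if t["k_min"] < 1 or int(t["k_min"]) != t["k_min"]:
            raise ValueError("k_min must be a positive integer")
        n_cell = len(self.celline_specs())
        if n_cell and t["k_min"] > n_cell:
            raise ValueError(
                f"k_min={int(t['k_min'])} exceeds the {n_cell} cell-line dataset(s)")
        if t["min_peptides"] < 0 or t["min_fold"] <= 0:
            raise ValueError("min_peptides must be >= 0 and min_fold > 0")
        if not self.datasets:
            raise ValueError("no datasets configured")
        ids = [d.id for d in self.datasets]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate dataset ids")

    def celline_specs(self) -> list[DatasetSpec]:
        return [d for d in self.datasets if d.role == "cellline"]

    def tumour_specs(self) -> list[DatasetSpec]:
        return [d for d in self.datasets if d.role == "tumour"]

    def resolve(self, path: str | None) -> Path | None:
        return None if path is None else (self.base_dir / path)


_TOP_KEYS = {"datasets", "outdir", "seed", "hmg_up", "hmg_down", "gene_sets",
             "gene_sets_category", "proteomics", "delta_tables", "process_map",
             "thresholds", "modes"}
_DATASET_KEYS = {"id", "role", "contrast", "matrix", "groups", "annot", "geo2r"}


def validate_config(path) -> PipelineConfig:
    """Load and validate a pipeline YAML config.

    Unknown keys are rejected (typo safety), thresholds are checked for
    range, k_min is checked against the number of cell-line datasets, and
    every referenced path must exist.  Relative paths resolve against the
    config file's directory.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
    specs = []
    for entry in raw.get("datasets", []):
        extra = set(entry) - _DATASET_KEYS
        if extra:
            raise ValueError(f"{path}: unknown dataset key(s): {sorted(extra)}")
        contrast = entry.get("contrast")
        if not (isinstance(contrast, (list, tuple)) and len(contrast) == 2):
            raise ValueError(f"{path}: dataset {entry.get('id')}: contrast "
                             "must be a pair of group labels")
        specs.append(DatasetSpec(id=str(entry["id"]), role=entry.get("role", ""),
                                 contrast=(str(contrast[0]), str(contrast[1])),
                                 matrix=entry.get("matrix"), groups=entry.get("groups"),
                                 annot=entry.get("annot"), geo2r=entry.get("geo2r")))
    config = PipelineConfig(
        datasets=specs,
        outdir=str(raw.get("outdir", "mimicmap_out")),
        seed=int(raw.get("seed", 0)),
        hmg_up=raw.get("hmg_up"), hmg_down=raw.get("hmg_down"),
        gene_sets=raw.get("gene_sets"),
        gene_sets_category=str(raw.get("gene_sets_category", "pathway")),
        proteomics=raw.get("proteomics"),
        delta_tables=dict(raw.get("delta_tables", {})),
        process_map=raw.get("process_map"),
        thresholds=dict(raw.get("thresholds", {})),
        modes=dict(raw.get("modes", {})),
        base_dir=path.parent,
    )
    for spec in config.datasets:
        for attr in ("matrix", "groups", "annot", "geo2r"):
            p = getattr(spec, attr)
            if p is not None and not (config.base_dir / p).exists():
                raise ValueError(f"{path}: dataset {spec.id}: missing file {p}")
    for attr in ("hmg_up", "hmg_down", "gene_sets", "proteomics", "process_map"):
        p = getattr(config, attr)
        if p is not None and not (config.base_dir / p).exists():
            raise ValueError(f"{path}: missing file {p}")
    for ds_id, p in config.delta_tables.items():
        if not (config.base_dir / p).exists():
            raise ValueError(f"{path}: delta table {ds_id}: missing file {p}")
    return config


def _config_hash(config: PipelineConfig) -> str:
    payload = {
        "datasets": [{k: getattr(d, k) if k != "contrast" else list(d.contrast)
                      for k in sorted(_DATASET_KEYS)} for d in config.datasets],
        "thresholds": config.thresholds,
        "modes": config.modes,
        "seed": config.seed,
        "hmg_up": config.hmg_up, "hmg_down": config.hmg_down,
        "gene_sets": config.gene_sets, "proteomics": config.proteomics,
        "delta_tables": config.delta_tables, "process_map": config.process_map,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True,
                                     default=str).encode()).hexdigest()


def _load_delta_table(path) -> dict[str, float]:
    frame = pd.read_csv(path, sep="\t")
    sym_col, val_col = frame.columns[0], frame.columns[1]
    return {normalize_symbol(g): float(v)
            for g, v in zip(frame[sym_col], frame[val_col])}


def run_pipeline(config: PipelineConfig,
                 stages: Sequence[str] | None = None) -> dict[str, Any]:
    """Execute the configured stages and write the report bundle.

    Returns a dict of in-memory results keyed by stage.  Any stage error is
    re-raised annotated with the stage name.  Skipped stages leave their
    outputs absent and are recorded as skipped in the manifest.
    """
    selected = list(STAGES) if stages is None else list(stages)
    bad = set(selected) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stage(s): {sorted(bad)}")
    outdir = Path(config.base_dir) / config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    t = config.thresholds
    modes = config.modes
    results: dict[str, Any] = {}
    accounting: dict[str, Any] = {}
    summary: list[tuple[str, float]] = []

    def stage_enabled(name: str) -> bool:
        return name in selected

    def fail(stage: str, exc: Exception):
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # ---- diffexpr -----------------------------------------------------
    tables: dict[str, DiffExprTable] = {}
    if stage_enabled("diffexpr"):
        try:
            for spec in config.datasets:
                if spec.geo2r is not None:
                    table = read_geo2r_table(config.resolve(spec.geo2r),
                                             spec.id, spec.contrast)
                else:
                    dataset = read_expression_dataset(
                        config.resolve(spec.matrix), config.resolve(spec.groups),
                        config.resolve(spec.annot), dataset_id=spec.id,
                        log2_transform=modes["log2_transform"])
                    table = diffexpr_table(dataset, spec.contrast,
                                           statistic=modes["statistic"])
                tables[spec.id] = table
                write_diffexpr_table(table, outdir / f"diffexpr_{spec.id}.tsv")
                accounting[f"diffexpr_{spec.id}"] = {
                    "genes": int(len(table.rows)),
                    "ambiguous": int(table.rows["ambiguous"].sum()),
                    "significant": int(len(table.significant(t["alpha"]))),
                }
                logger.info("diffexpr %s: %d genes (%d significant at alpha=%g)",
                            spec.id, len(table.rows),
                            len(table.significant(t["alpha"])), t["alpha"])
            results["diffexpr"] = tables
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            fail("diffexpr", exc)

    cell_tables = [tables[s.id] for s in config.celline_specs() if s.id in tables]
    tumour_tables = [tables[s.id] for s in config.tumour_specs() if s.id in tables]

    # ---- consensus ----------------------------------------------------
    consensus_up = consensus_down = None
    if stage_enabled("consensus") and cell_tables:
        try:
            consensus_up, consensus_down, excluded = consensus_pair(
                cell_tables, k_min=int(t["k_min"]), alpha=t["alpha"])
            for cs, name in ((consensus_up, "up"), (consensus_down, "down")):
                write_tsv(cs.to_frame(), outdir / f"consensus_{name}.tsv")
            core_up = top_core_genes(cell_tables, "up", int(t["top_n"]), t["alpha_adj"])
            core_down = top_core_genes(cell_tables, "down", int(t["top_n"]), t["alpha_adj"])
            write_tsv(pd.DataFrame({"symbol": core_up + core_down,
                                    "direction": ["up"] * len(core_up)
                                    + ["down"] * len(core_down)}),
                      outdir / "core_genes.tsv")
            results["consensus"] = {"up": consensus_up, "down": consensus_down,
                                    "excluded": excluded,
                                    "core_up": core_up, "core_down": core_down}
            accounting["consensus"] = {
                "up": len(consensus_up), "down": len(consensus_down),
                "excluded_both_directions": len(excluded),
                "core_up": len(core_up), "core_down": len(core_down)}
            summary += [("consensus_up", len(consensus_up)),
                        ("consensus_down", len(consensus_down)),
                        ("core_up", len(core_up)), ("core_down", len(core_down))]
            logger.info("consensus: %d up / %d down (k>=%d, alpha=%g); "
                        "core top-%d: %d up / %d down",
                        len(consensus_up), len(consensus_down), int(t["k_min"]),
                        t["alpha"], int(t["top_n"]), len(core_up), len(core_down))
        except Exception as exc:
            fail("consensus", exc)

    # ---- z-rank -------------------------------------------------------
    zrank = None
    if stage_enabled("zrank") and consensus_up is not None and tumour_tables:
        try:
            profiles = {tb.dataset_id: zscore_fold(tb, alpha=t["alpha"])
                        for tb in tumour_tables}
            genes = sorted(consensus_up.genes | consensus_down.genes)
            zrank = average_z_rank(profiles, genes)
            write_tsv(zrank, outdir / "zscore_rank.tsv")
            results["zrank"] = zrank
            accounting["zrank"] = {"genes": int(len(zrank))}
        except Exception as exc:
            fail("zrank", exc)

    # ---- concordance --------------------------------------------------
    calls = None
    if stage_enabled("concordance") and consensus_up is not None and tumour_tables:
        try:
            calls = []
            for cs in (consensus_up, consensus_down):
                if cs.members:
                    calls += classify_concordance(cs, tumour_tables,
                                                  alpha=t["alpha"])
            frame = calls_to_frame(calls)
            write_tsv(frame, outdir / "concordance.tsv")
            counts = frame["call"].value_counts()
            results["concordance"] = calls
            accounting["concordance"] = {k: int(v) for k, v in counts.items()}
            summary += [("concordant", int(counts.get("concordant", 0))),
                        ("discordant", int(counts.get("discordant", 0))),
                        ("unclassified", int(counts.get("unclassified", 0)))]
            logger.info("concordance: %s", dict(counts))
        except Exception as exc:
            fail("concordance", exc)

    # ---- mimicry ------------------------------------------------------
    assignments = None
    if (stage_enabled("mimicry") and config.hmg_up and config.hmg_down
            and len(config.delta_tables) == 2):
        try:
            hmg_up = read_hmg_list(config.resolve(config.hmg_up), "up")
            hmg_down = read_hmg_list(config.resolve(config.hmg_down), "down")
            check_hmg_pair(hmg_up, hmg_down)
            deltas = {ds: _load_delta_table(config.resolve(p))
                      for ds, p in config.delta_tables.items()}
            protein_folds = None
            if config.proteomics:
                prot = read_proteomics_table(config.resolve(config.proteomics))
                prot = filter_significant_proteins(prot, int(t["min_peptides"]),
                                                   0.05)
                protein_folds = prot.fold_by_gene()
            assignments = assign_hmg_mimicry(
                hmg_up, hmg_down, deltas, protein_folds,
                protein_veto=bool(modes["protein_veto"]))
            frame = assignments_to_frame(assignments)
            write_tsv(frame, outdir / "mimicry.tsv")
            counts = frame["assigned_to"].value_counts()
            if config.process_map:
                pm_frame = pd.read_csv(config.resolve(config.process_map), sep="\t")
                process_map = dict(zip(pm_frame.iloc[:, 0], pm_frame.iloc[:, 1]))
                write_tsv(aggregate_by_process(assignments, process_map),
                          outdir / "mimicry_by_process.tsv")
            results["mimicry"] = assignments
            accounting["mimicry"] = {k: int(v) for k, v in counts.items()}
            summary += [("mimicry_HLE", int(counts.get("HLE", 0))),
                        ("mimicry_HUH7", int(counts.get("HUH7", 0)))]
            logger.info("mimicry: %s", dict(counts))
        except Exception as exc:
            fail("mimicry", exc)

    # ---- enrichment ---------------------------------------------------
    if (stage_enabled("enrichment") and config.gene_sets
            and consensus_up is not None and cell_tables):
        try:
            collection = read_gmt(config.resolve(config.gene_sets),
                                  category=config.gene_sets_category)
            universe = set(cell_tables[0].rows["symbol"])
            for tb in cell_tables[1:]:
                universe &= set(tb.rows["symbol"])
            enr = {}
            for cs, name in ((consensus_up, "up"), (consensus_down, "down")):
                if not cs.members:
                    continue
                rows = hypergeom_enrich(cs.genes, collection, universe,
                                        mode=modes["enrichment"])
                write_tsv(rows, outdir / f"enrichment_{name}.tsv")
                top = select_top_terms(rows, t["p_max"], t["fdr_max"],
                                       n_pathway=10, n_go=5)
                write_tsv(top, outdir / f"enrichment_{name}_top.tsv")
                enr[name] = rows
            results["enrichment"] = enr
            accounting["enrichment"] = {
                name: int((rows["p"] < t["p_max"]).sum())
                for name, rows in enr.items()}
        except Exception as exc:
            fail("enrichment", exc)

    # ---- proteomics ---------------------------------------------------
    if stage_enabled("proteomics") and config.proteomics:
        try:
            table = read_proteomics_table(config.resolve(config.proteomics))
            filtered = filter_significant_proteins(table, int(t["min_peptides"]),
                                                   0.05)
            hle, huh7 = top_fold_proteins(filtered, int(t["top_proteins"]),
                                          t["min_fold"])
            write_tsv(hle, outdir / "proteins_hle_higher.tsv")
            write_tsv(huh7, outdir / "proteins_huh7_higher.tsv")
            agreement = None
            if assignments is not None:
                agree_frame, fraction = gene_protein_agreement(assignments, filtered)
                write_tsv(agree_frame, outdir / "gene_protein_agreement.tsv")
                agreement = fraction
                summary.append(("gene_protein_agreement", round(fraction, 6)))
            results["proteomics"] = {"filtered": filtered, "hle": hle,
                                     "huh7": huh7, "agreement": agreement}
            accounting["proteomics"] = {
                "input": len(table), "significant": len(filtered),
                "top_hle": len(hle), "top_huh7": len(huh7)}
        except Exception as exc:
            fail("proteomics", exc)

    # ---- manifest and summary ----------------------------------------
    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "stages_run": [s for s in STAGES if s in selected],
        "stages_skipped": [s for s in STAGES if s not in selected],
        "thresholds": config.thresholds,
        "modes": config.modes,
        "accounting": accounting,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    write_tsv(pd.DataFrame(summary, columns=["quantity", "value"]),
              outdir / "summary.tsv")
    results["manifest"] = manifest
    results["summary"] = dict(summary)
    return results
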