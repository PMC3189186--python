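"""End-to-end orchestration: pI table -> shift analysis -> enrichment -> parsimony.

Stages are optional and driven by which inputs the manifest names; every
run emits a metadata JSON sufficient to reproduce it.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import pandas as pd

from . import __version__
from .config import Config, load_keyvalue_file
from .isoelectric import (
    DEFAULT_PKA_TABLE,
    PTMChargeModel,
    build_groups,
    load_pka_table,
    net_charge,
    protein_pi,
)
from .seqio import (
    apply_signal_cleavage,
    read_alignment,
    read_cleavage_table,
    read_fasta,
    read_ptm_table,
    read_selection_table,
)
from .selection_enrichment import (
    call_selected_sites,
    classify_alignment_charges,
    enrichment_test,
)
from .shift_analysis import (
    OrthologPISet,
    SpeciesTree,
    discretize_pi,
    fitch_shift_count,
    flag_shifters,
    pairwise_diffs,
    permutation_pvalue,
    shift_threshold,
)

__all__ = ["PipelineError", "load_manifest", "build_pi_table", "run_pipeline"]

logger = logging.getLogger("pishift")

MANIFEST_KEYS = {
    "fasta", "cleavage", "ptm", "alignment", "alignment_format",
    "selection_table", "ref_species", "species_a", "species_b", "tree",
}


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def load_manifest(path: str | Path) -> dict:
    manifest = load_keyvalue_file(path)
    unknown = set(manifest) - MANIFEST_KEYS
    if unknown:
        raise PipelineError("manifest", f"unknown manifest key(s): {', '.join(sorted(unknown))}")
    if "fasta" not in manifest:
        raise PipelineError("manifest", "manifest must name a 'fasta' input")
    return manifest


def _ptm_model(config: Config) -> PTMChargeModel:
    return PTMChargeModel(
        phospho_pkas=(config.phospho_pka1, config.phospho_pka2),
        sialic_per_glyco=config.sialic_per_glyco,
        sialic_pka=config.sialic_pka,
    )


def _pka_table(config: Config):
    if config.pka_table == "builtin":
        return DEFAULT_PKA_TABLE
    return load_pka_table(config.pka_table)


def build_pi_table(
    fasta: str | Path,
    config: Config,
    cleavage: str | Path | None = None,
    ptm: str | Path | None = None,
) -> pd.DataFrame:
    """Per-protein pI table (id, species, family, length, pI, net_charge_at_pH7)."""
    table = _pka_table(config)
    model = _ptm_model(config)
    records = read_fasta(fasta, delimiter=config.header_delimiter)
    cleavage_map = read_cleavage_table(cleavage) if cleavage else {}
    ptm_map = read_ptm_table(ptm) if ptm else {}
    rows = []
    for rec in records:
        if ptm_map.get(rec.id):
            rec.ptms = list(ptm_map[rec.id])
        pos = cleavage_map.get(rec.id, 0)
        if cleavage and rec.id not in cleavage_map:
            logger.warning("no cleavage entry for %s; assuming no signal peptide", rec.id)
        mature = apply_signal_cleavage(rec, pos)
        pi = protein_pi(
            mature, table=table, use_ptms=config.use_ptms,
            ptm_model=model, precision=config.precision,
        )
        groups = build_groups(
            mature.sequence, table, mature.ptms if config.use_ptms else (), model
        )
        rows.append({
            "id": mature.id,
            "species": mature.species,
            "family": mature.family,
            "length": len(mature.sequence),
            "pI": pi,
            "net_charge_at_pH7": round(net_charge(groups, 7.0), 4),
        })
    return pd.DataFrame(rows, columns=["id", "species", "family", "length", "pI", "net_charge_at_pH7"])


def build_shift_table(piset: OrthologPISet, a: str, b: str, config: Config) -> pd.DataFrame:
    """Shift table for one species pair; permutation p only for flagged families."""
    diffs = pairwise_diffs(piset, a, b)
    if len(diffs) < 4:
        raise PipelineError("shift", f"only {len(diffs)} families shared by {a!r}/{b!r}; need >= 4")
    threshold = shift_threshold(diffs.values())
    result = flag_shifters(diffs, threshold, species_pair=(a, b))
    rows = []
    for family in sorted(diffs):
        flagged = family in result.flagged
        pvalue = ""
        if flagged:
            pvalue = permutation_pvalue(
                piset, a, b, family,
                n_perm=config.n_perm, seed=config.seed, mode=config.perm_mode,
            )
        rows.append({
            "family": family,
            "abs_diff": round(diffs[family], 4),
            "flagged": flagged,
            "perm_pvalue": pvalue,
        })
    frame = pd.DataFrame(rows, columns=["family", "abs_diff", "flagged", "perm_pvalue"])
    frame.attrs["threshold"] = threshold
    return frame


def run_pipeline(config: Config, manifest: dict, out_dir: str | Path) -> dict:
    """Run every stage the manifest enables; return the report summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}

    # Stage 1: per-protein pI (always runs).
    try:
        pi_table = build_pi_table(
            manifest["fasta"], config,
            cleavage=manifest.get("cleavage"), ptm=manifest.get("ptm"),
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("pi", str(exc)) from exc
    pi_path = out / "pi_table.tsv"
    pi_table.to_csv(pi_path, sep="\t", index=False)
    report["stages"]["pi"] = {"status": "ok", "n_proteins": int(len(pi_table)), "out": pi_path.name}
    logger.info("pi stage: %d proteins", len(pi_table))

    # Stage 2: shift analysis (needs a species pair).
    a, b = manifest.get("species_a"), manifest.get("species_b")
    if a and b:
        try:
            piset = OrthologPISet.from_table(pi_table)
            shift_table = build_shift_table(piset, a, b, config)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("shift", str(exc)) from exc
        shift_path = out / "shift_table.tsv"
        shift_table.to_csv(shift_path, sep="\t", index=False)
        report["stages"]["shift"] = {
            "status": "ok",
            "species_pair": [a, b],
            "threshold": round(float(shift_table.attrs["threshold"]), 6),
            "n_flagged": int(shift_table["flagged"].sum()),
            "out": shift_path.name,
        }
        logger.info(
            "shift stage: threshold %.4f, %d flagged",
            shift_table.attrs["threshold"], int(shift_table["flagged"].sum()),
        )
    else:
        report["stages"]["shift"] = {"status": "not run", "reason": "no species pair in manifest"}

    # Stage 3: selection enrichment (needs alignment + selection table + ref species).
    if manifest.get("alignment") and manifest.get("selection_table"):
        ref = manifest.get("ref_species")
        if not ref:
            raise PipelineError("enrichment", "manifest names an alignment but no ref_species")
        try:
            aln = read_alignment(
                manifest["alignment"],
                format=manifest.get("alignment_format", "fasta"),
                delimiter=config.header_delimiter,
            )
            sites = read_selection_table(manifest["selection_table"])
            selected = call_selected_sites(sites, alpha=config.alpha)
            classes = classify_alignment_charges(aln, ref)
            enrichment = enrichment_test(selected, classes)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("enrichment", str(exc)) from exc
        payload = enrichment.as_dict()
        payload["parameters"] = {"alpha": config.alpha, "ref_species": ref, "test": enrichment.test}
        enrich_path = out / "enrichment.json"
        enrich_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        report["stages"]["enrichment"] = {"status": "ok", "pvalue": enrichment.fisher_p, "out": enrich_path.name}
        logger.info("enrichment stage: p=%.3g", enrichment.fisher_p)
    else:
        report["stages"]["enrichment"] = {"status": "not run", "reason": "no alignment/selection table"}

    # Stage 4: parsimony on the species tree (needs a tree).
    if manifest.get("tree"):
        try:
            tree = SpeciesTree.from_newick(Path(manifest["tree"]))
            leaves = set(tree.leaf_labels())
            piset = OrthologPISet.from_table(pi_table)
            bounds = (config.bounds_low, config.bounds_high)
            rows = []
            for family in sorted(piset.families):
                values = piset.families[family]
                if not leaves.issubset(values):
                    continue  # family must cover every leaf
                states = {sp: discretize_pi(values[sp], bounds) for sp in leaves}
                rows.append({
                    "family": family,
                    "n_species": len(leaves),
                    "min_changes": fitch_shift_count(tree, states),
                })
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("parsimony", str(exc)) from exc
        parsimony_path = out / "parsimony.tsv"
        pd.DataFrame(rows, columns=["family", "n_species", "min_changes"]).to_csv(
            parsimony_path, sep="\t", index=False
        )
        report["stages"]["parsimony"] = {"status": "ok", "n_families": len(rows), "out": parsimony_path.name}
        logger.info("parsimony stage: %d families", len(rows))
    else:
        report["stages"]["parsimony"] = {"status": "not run", "reason": "no tree in manifest"}

    metadata = {
        "config": config.as_dict(),
        "manifest": dict(manifest),
        "seed": config.seed,
        "versions": {
            "pishift": __version__,
            "python": platform.python_version(),
        },
        "report": report,
    }
    (out / "run_metadata.json").write_text(json.dumps(metadata, indent=2, sort_keys=True) + "\n")
    return report
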