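"""End-to-end orchestration and file-format glue.

Ties the stages together for a cohort of matched tumour-normal count
tables: constitutional and somatic calling, linked-artefact exclusion,
haplogroup assignment and private-variant derivation, heteroplasmy
shift pairing, functional annotation, mutational spectra and cohort
statistics.  Emits a VCF plus flat TSV/JSON mirrors; all outputs are
deterministic given the inputs and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import haplogroups as hg
from .calling import (CALL_COLUMNS, CallingThresholds, call_constitutional,
                      call_somatic, flag_linked_artefacts)
from .cohort import region_distribution_test, summarize_cohort
from .dynamics import PAIR_COLUMNS, pair_heteroplasmies, shift_report
from .reference import (GENOME_LENGTH, MitoGenome, RegionMap,
                        default_region_map, load_gene_table, load_reference,
                        build_region_map)
from .spectrum import (annotate_variants, build_96_spectrum,
                       build_strand_spectrum)

logger = logging.getLogger("mitovar")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, sample: str, original: Exception):
        super().__init__(f"stage {stage!r} failed for sample {sample!r}: "
                         f"{original}")
        self.stage = stage
        self.sample = sample


@dataclass
class PipelineConfig:
    thresholds: CallingThresholds = field(default_factory=CallingThresholds)
    reference_fasta: str | Path | None = None     # None = packaged
    gene_table: str | Path | None = None
    phylotree: str | Path | None = None
    haplogroup_overrides: dict[str, str] = field(default_factory=dict)
    normalize_vac_diff: bool = True
    welch: bool = False
    log_frequency: bool = False
    bh_correction: bool = True
    artefact_cooccurrence_min: float = 0.95
    seed: int = 0

    def load_reference(self) -> MitoGenome:
        return load_reference(self.reference_fasta)

    def load_region_map(self) -> RegionMap:
        if self.gene_table is None:
            return default_region_map()
        return build_region_map(load_gene_table(self.gene_table))

    def load_tree(self) -> hg.Phylotree:
        return hg.load_phylotree(self.phylotree)


@dataclass
class PipelineResult:
    calls: pd.DataFrame             # all calls, annotated, private-flagged
    haplogroups: pd.DataFrame       # per normal sample
    heteroplasmy_pairs: pd.DataFrame
    shift: dict | None
    cohort_summary: pd.DataFrame
    region_tests: dict
    artefact_flags: pd.DataFrame
    stage_counts: dict


def _calls_to_variant_set(calls: pd.DataFrame) -> list[hg.Variant]:
    return [(int(r.pos), r.ref, r.alt) for r in calls.itertuples()]


def run_pipeline(config: PipelineConfig,
                 manifest: pd.DataFrame,
                 counts: dict[str, pd.DataFrame],
                 observations: dict[str, pd.DataFrame] | None = None,
                 candidate_artefacts=None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full analysis over a cohort.

    ``manifest`` has columns pair_id/normal_sample/tumour_sample;
    ``counts`` maps each sample id to its strand-split count table;
    ``observations`` optionally maps sample ids to read-level
    observation tables for artefact flagging of ``candidate_artefacts``
    pairs.  An empty manifest produces empty outputs with a warning.
    """
    genome = config.load_reference()
    region_map = config.load_region_map()
    tree = config.load_tree()
    t = config.thresholds
    stage_counts: dict[str, int] = {
        "pairs": len(manifest), "sites_read": 0,
        "constitutional_calls": 0, "somatic_calls": 0,
        "private_variants": 0, "heteroplasmy_pairs": 0,
        "artefact_flagged": 0,
    }
    if manifest.empty:
        logger.warning("empty manifest: producing empty outputs")

    all_calls: list[pd.DataFrame] = []
    haplo_rows = []
    pair_tables = []
    artefact_rows = []

    for rec in manifest.itertuples():
        pair_id = rec.pair_id
        nid, tid = rec.normal_sample, rec.tumour_sample
        try:
            normal = counts[nid]
            tumour = counts[tid]
        except KeyError as e:
            raise PipelineError("load_counts", str(e.args[0]), e) from e
        stage_counts["sites_read"] += len(normal) + len(tumour)

        try:
            const = call_constitutional(normal, t, tissue="normal")
        except Exception as e:  # pragma: no cover - defensive
            raise PipelineError("call_constitutional", nid, e) from e
        try:
            som = call_somatic(tumour, normal, t,
                               normalize_vac_diff=config.normalize_vac_diff)
        except Exception as e:  # pragma: no cover - defensive
            raise PipelineError("call_somatic", tid, e) from e

        # linked-artefact exclusion
        excluded: set[tuple[int, str]] = set()
        if observations and candidate_artefacts:
            for sid in (nid, tid):
                obs = observations.get(sid)
                if obs is None or obs.empty:
                    continue
                flags = flag_linked_artefacts(
                    obs, candidate_artefacts,
                    cooccurrence_min=config.artefact_cooccurrence_min)
                flags.insert(0, "sample_id", sid)
                artefact_rows.append(flags)
                for fr in flags.loc[flags["flagged"]].itertuples():
                    excluded.add((fr.pos1, fr.alt1))
                    excluded.add((fr.pos2, fr.alt2))
        if excluded:
            stage_counts["artefact_flagged"] += len(excluded)
            keep = ~const.apply(
                lambda r: (r["pos"], r["alt"]) in excluded, axis=1)
            const = const.loc[keep] if not const.empty else const
            keep = ~som.apply(
                lambda r: (r["pos"], r["alt"]) in excluded, axis=1)
            som = som.loc[keep] if not som.empty else som

        stage_counts["constitutional_calls"] += len(const)
        stage_counts["somatic_calls"] += len(som)

        # haplogroup + private derivation on the normal
        variant_set = _calls_to_variant_set(const)
        if nid in config.haplogroup_overrides:
            label = config.haplogroup_overrides[nid]
            call = hg.HaplogroupCall(
                haplogroup=label, score=0,
                path_variants=tree.path_variants(label))
        elif variant_set:
            call = hg.assign_haplogroup(variant_set, tree)
        else:
            call = hg.HaplogroupCall(haplogroup=tree.root, score=0,
                                     path_variants=())
        private = set(map(tuple, hg.derive_private(variant_set, call)))
        haplo_rows.append({"sample_id": nid, "pair_id": pair_id,
                           "haplogroup": call.haplogroup,
                           "score": call.score})
        const = const.copy()
        const["private"] = [
            (int(r.pos), r.ref, r.alt) in private
            for r in const.itertuples()]
        som = som.copy()
        som["private"] = False
        stage_counts["private_variants"] += int(const["private"].sum())

        const["pair_id"] = pair_id
        som["pair_id"] = pair_id
        all_calls.extend([const, som])

        # heteroplasmy pairing against raw tumour counts
        pairs = pair_heteroplasmies(const, tumour, t, pair_id=pair_id)
        stage_counts["heteroplasmy_pairs"] += len(pairs)
        pair_tables.append(pairs)

    call_cols = list(CALL_COLUMNS) + ["private", "pair_id"]
    calls = (pd.concat(all_calls, ignore_index=True)[call_cols]
             if all_calls else pd.DataFrame(columns=call_cols))
    pair_tables = [p for p in pair_tables if not p.empty]
    het_pairs = (pd.concat(pair_tables, ignore_index=True)
                 if pair_tables else pd.DataFrame(columns=PAIR_COLUMNS))
    artefacts = (pd.concat(artefact_rows, ignore_index=True)
                 if artefact_rows else pd.DataFrame())

    if not calls.empty:
        calls = annotate_variants(calls, region_map, genome)
        calls = calls.sort_values(["pair_id", "sample_id", "pos", "alt"],
                                  ignore_index=True)

    shift = None
    if len(het_pairs) >= 2:
        shift = shift_report(het_pairs, t).to_dict()

    summary = summarize_cohort(
        calls if not calls.empty
        else pd.DataFrame(columns=call_cols + ["region"]), manifest)

    region_tests = {}
    if not calls.empty:
        priv = calls.loc[(calls["origin"] == "constitutional")
                         & calls["private"]]
        som_all = calls.loc[calls["origin"] == "somatic"]
        for label, sub in (("private_constitutional", priv),
                           ("somatic", som_all)):
            if len(sub) >= 1:
                region_tests[label] = region_distribution_test(
                    sub, region_map).to_dict()

    result = PipelineResult(
        calls=calls,
        haplogroups=pd.DataFrame(haplo_rows,
                                 columns=["sample_id", "pair_id",
                                          "haplogroup", "score"]),
        heteroplasmy_pairs=het_pairs, shift=shift,
        cohort_summary=summary, region_tests=region_tests,
        artefact_flags=artefacts, stage_counts=stage_counts)
    for stage, n in stage_counts.items():
        logger.info("%s: %d", stage, n)
    if out_dir is not None:
        write_results(result, out_dir)
    return result


def write_results(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.calls.to_csv(out / "calls.tsv", sep="\t", index=False)
    write_vcf(result.calls, out / "calls.vcf")
    result.haplogroups.to_csv(out / "haplogroups.tsv", sep="\t", index=False)
    result.heteroplasmy_pairs.to_csv(out / "heteroplasmy_pairs.tsv",
                                     sep="\t", index=False)
    result.cohort_summary.to_csv(out / "cohort_summary.tsv", sep="\t")
    if not result.artefact_flags.empty:
        result.artefact_flags.to_csv(out / "artefact_flags.tsv", sep="\t",
                                     index=False)
    summary = {
        "stage_counts": result.stage_counts,
        "shift": result.shift,
        "region_tests": result.region_tests,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_safe)


def _json_safe(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


# ---------------------------------------------------------------------------
# VCF output (contig chrM on rCRS coordinates)
# ---------------------------------------------------------------------------

_VCF_INFO_FIELDS = [
    ("SAMPLE", "String", "Sample identifier"),
    ("TISSUE", "String", "Tissue of the call (normal/tumour)"),
    ("VAC", "Integer", "Variant allele count"),
    ("VAF", "Float", "Variant allele fraction"),
    ("FVAC", "Integer", "Forward-strand variant allele count"),
    ("RVAC", "Integer", "Reverse-strand variant allele count"),
    ("DP", "Integer", "Read depth at the site"),
    ("ORIGIN", "String", "constitutional or somatic"),
    ("ZYGOSITY", "String", "heteroplasmy or homoplasmy"),
    ("PRIVATE", "Integer", "1 if a private constitutional variant"),
    ("GENE", "String", "Gene(s) covering the position"),
    ("REGION", "String", "Functional region"),
    ("CSQ", "String", "Consequence class"),
]


def write_vcf(calls: pd.DataFrame, path: str | Path,
              source: str = "mitovar") -> None:
    """Write calls as VCF 4.2 with per-call INFO annotation.

    Records are sorted by position (then sample); duplicate
    (sample, pos, ref, alt) records are an error.
    """
    if not calls.empty:
        dup = calls.duplicated(subset=["sample_id", "pos", "ref", "alt"])
        if dup.any():
            raise ValueError("duplicate call records for VCF output")
        calls = calls.sort_values(["pos", "sample_id", "alt"])
    lines = ["##fileformat=VCFv4.2",
             f"##source={source}",
             f"##contig=<ID=chrM,length={GENOME_LENGTH}>"]
    for key, typ, desc in _VCF_INFO_FIELDS:
        lines.append(f'##INFO=<ID={key},Number=1,Type={typ},'
                     f'Description="{desc}">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for rec in calls.itertuples():
        info = [
            f"SAMPLE={rec.sample_id}", f"TISSUE={rec.tissue}",
            f"VAC={int(rec.vac)}", f"VAF={rec.vaf:.6g}",
            f"FVAC={int(rec.fwd_vac)}", f"RVAC={int(rec.rev_vac)}",
            f"DP={int(rec.depth)}", f"ORIGIN={rec.origin}",
            f"ZYGOSITY={rec.zygosity}",
        ]
        if hasattr(rec, "private"):
            info.append(f"PRIVATE={int(bool(rec.private))}")
        for attr, key in (("gene", "GENE"), ("region", "REGION"),
                          ("consequence", "CSQ")):
            if hasattr(rec, attr):
                value = str(getattr(rec, attr)).replace(" ", "_")
                if value:
                    info.append(f"{key}={value}")
        lines.append("\t".join([
            "chrM", str(int(rec.pos)), ".", rec.ref, rec.alt, ".", "PASS",
            ";".join(info)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Read a VCF written by :func:`write_vcf` back into a call table."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _id, ref, alt, _q, _f, info = \
                line.rstrip("\n").split("\t")[:8]
            kv = dict(item.split("=", 1) for item in info.split(";")
                      if "=" in item)
            row = {
                "sample_id": kv.get("SAMPLE"), "tissue": kv.get("TISSUE"),
                "pos": int(pos), "ref": ref, "alt": alt,
                "vac": int(kv["VAC"]), "depth": int(kv["DP"]),
                "vaf": float(kv["VAF"]), "fwd_vac": int(kv["FVAC"]),
                "rev_vac": int(kv["RVAC"]), "zygosity": kv.get("ZYGOSITY"),
                "origin": kv.get("ORIGIN"),
            }
            if "PRIVATE" in kv:
                row["private"] = bool(int(kv["PRIVATE"]))
            for key, col in (("GENE", "gene"), ("REGION", "region"),
                             ("CSQ", "consequence")):
                if key in kv:
                    row[col] = kv[key].replace("_", " ")
            rows.append(row)
    return pd.DataFrame(rows)
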