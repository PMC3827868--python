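"""End-to-end orchestration: clean -> annotate -> catalog -> isomiR/edit ->
differential expression -> targets, with one config and one seed.

The whole run is a pure function of (inputs, config, seed): stage outputs
are written as TSV/FASTA/BED text files and summarized in a JSON report
whose canonical checksum is byte-stable across runs. Read-count
conservation is asserted between stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml

from . import annotate as ann
from . import catalog as cat
from . import de as de_mod
from . import isomir as iso
from . import reads as rd
from . import targets as tg
from .fold import get_fold_engine
from .io import ensure_dir, read_fasta, write_bed6, write_fasta, write_tags_fasta
from .refs import MatureMiRNA, Precursor, ReferenceBundle

log = logging.getLogger("srnakit")

__all__ = ["RunConfig", "run_all", "report_checksum", "load_references"]


@dataclass
class RunConfig:
    """All stage parameters with their documented defaults.

    Paths may stay empty when the pipeline is fed in-memory objects.
    Round-trips unchanged through YAML.
    """

    fastq_a: str = ""
    fastq_b: str = ""
    mature_fasta: str = ""
    precursor_fasta: str = ""
    contaminant_fasta: str = ""
    genome_fasta: str = ""
    transcript_fasta: str = ""

    adapter: str = "TGGAATTCTCGG"
    min_len: int = 18
    max_len: int = 30
    quality_floor: float = 20.0
    conserved_max_mismatch: int = 2
    genome_max_mismatch: int = 1
    fc_threshold: float = 1.0
    alpha: float = 0.05
    fold_engine: str = "vienna"
    duplex_engine: str = "vienna"
    mfe_ceiling: float = -18.0
    flank_proximal: int = 20
    flank_distal: int = 160
    rng_seed: int = 0

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as out:
            yaml.safe_dump(asdict(self), out, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def load_references(
    config: RunConfig,
) -> Tuple[List[MatureMiRNA], List[Precursor], List[Tuple[str, str, str]], Dict[str, str], List[Tuple[str, str]]]:
    """Load reference FASTA files into typed records.

    The arm of each mature is derived from its position on the containing
    precursor (midpoint in the first half -> 5p, else 3p). Contaminant
    headers carry their class as ``id|class``.
    """
    for path in (config.mature_fasta, config.genome_fasta):
        if path and not os.path.exists(path):
            raise FileNotFoundError(path)
    precursors = []
    for pid, seq in read_fasta(config.precursor_fasta) if config.precursor_fasta else []:
        rna = seq.upper().replace("T", "U")
        precursors.append(Precursor(pid, rna, (0, 0), (0, 0), ""))
    matures = []
    for mid, seq in read_fasta(config.mature_fasta) if config.mature_fasta else []:
        rna = seq.upper().replace("T", "U")
        prec_id, arm = "", ""
        for prec in precursors:
            start = prec.sequence.find(rna)
            if start >= 0:
                prec_id = prec.precursor_id
                midpoint = start + len(rna) / 2
                arm = "5p" if midpoint <= len(prec.sequence) / 2 else "3p"
                break
        matures.append(MatureMiRNA(mid, rna, prec_id, arm))
    contaminants = []
    if config.contaminant_fasta:
        for rid, seq in read_fasta(config.contaminant_fasta):
            name, _, cls = rid.partition("|")
            contaminants.append((name, cls or "repeat", seq))
    genome = dict(read_fasta(config.genome_fasta)) if config.genome_fasta else {}
    transcripts = (
        read_fasta(config.transcript_fasta) if config.transcript_fasta else []
    )
    return matures, precursors, contaminants, genome, transcripts


def _round(obj):
    if isinstance(obj, float):
        return round(obj, 10)
    if isinstance(obj, dict):
        return {str(k): _round(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v) for v in obj]
    if hasattr(obj, "item"):
        return _round(obj.item())
    return obj


def report_checksum(report: Dict) -> str:
    payload = json.dumps(_round(report), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def run_all(
    config: RunConfig,
    outdir: str,
    bundle: Optional[ReferenceBundle] = None,
    reads_a=None,
    reads_b=None,
) -> Dict:
    """Run every stage and write all outputs under ``outdir``.

    Inputs come either from the config's file paths or, when ``bundle``
    (plus optional in-memory read lists) is given, from a simulated
    reference bundle directly.
    """
    ensure_dir(outdir)
    if bundle is not None:
        matures = bundle.all_products()
        precursors = bundle.precursor_set
        contaminants = [
            (c.contaminant_id, c.ncrna_class, c.sequence)
            for c in bundle.contaminant_set
        ]
        genome = bundle.genome
        transcripts = bundle.transcript_set
    else:
        matures, precursors, contaminants, genome, transcripts = load_references(config)
    if reads_a is None:
        if not config.fastq_a or not os.path.exists(config.fastq_a):
            raise FileNotFoundError(f"missing FASTQ: {config.fastq_a!r}")
        if not config.fastq_b or not os.path.exists(config.fastq_b):
            raise FileNotFoundError(f"missing FASTQ: {config.fastq_b!r}")
        reads_a, reads_b = config.fastq_a, config.fastq_b

    report: Dict = {"config": asdict(config)}

    # --- stage 1: clean + collapse -------------------------------------
    clean_a = rd.clean_reads(
        reads_a, config.adapter, config.min_len, config.max_len, config.quality_floor
    )
    clean_b = rd.clean_reads(
        reads_b, config.adapter, config.min_len, config.max_len, config.quality_floor
    )
    for name, res in (("A", clean_a), ("B", clean_b)):
        assert res.n_input == res.tally[rd.KEPT] + sum(
            v for k, v in res.tally.items() if k != rd.KEPT
        ), "read accounting violated"
        log.info("library %s: %d reads in, %d clean", name, res.n_input, len(res.reads))
    tags = rd.collapse_tags(clean_a.reads, clean_b.reads)
    n1 = max(1, len(clean_a.reads))
    n2 = max(1, len(clean_b.reads))
    write_tags_fasta(os.path.join(outdir, "tags.fasta"), tags)
    length_dist = rd.length_distribution(tags, config.min_len, config.max_len)
    report["cleaning"] = {
        "tally_a": clean_a.tally,
        "tally_b": clean_b.tally,
        "n_clean_a": len(clean_a.reads),
        "n_clean_b": len(clean_b.reads),
        "n_unique_tags": len(tags),
        "length_distribution": {int(k): float(v) for k, v in length_dist.items()},
    }

    # --- stage 2: annotation + genome mapping --------------------------
    records = ann.classify_ncrna(tags, contaminants)
    summary = ann.annotation_summary(records)
    summary.to_csv(os.path.join(outdir, "annotation_summary.tsv"), sep="\t")
    retained = [
        r.tag for r in records if r.category in ("mRNA_fragment", ann.UNANNOTATED)
    ]
    assert sum(t.total for t in tags) == int(
        summary[["reads_a", "reads_b"]].to_numpy().sum()
    ), "annotation accounting violated"
    report["annotation"] = {
        "summary": {
            idx: {k: int(v) for k, v in row.items()}
            for idx, row in summary.iterrows()
        },
        "n_retained_tags": len(retained),
    }

    # --- stage 3: conserved catalog ------------------------------------
    mirna_records, assignments = cat.identify_conserved(
        retained, matures, config.conserved_max_mismatch
    )
    families = cat.group_families(mirna_records)
    pairs = cat.pair_arms(mirna_records, precursors)
    bias = cat.first_base_bias(retained)
    report["catalog"] = {
        "n_conserved": len(mirna_records),
        "n_families": len(families),
        "n_arm_pairs": len(pairs),
        "first_base_bias": {
            int(L): {b: float(v) for b, v in row.items()}
            for L, row in bias.iterrows()
        },
    }
    pd.DataFrame(
        [
            (r.mature_id, r.sequence, r.precursor_id, r.arm, r.family,
             r.count_a, r.count_b)
            for r in mirna_records
        ],
        columns=["mature_id", "sequence", "precursor_id", "arm", "family",
                 "count_a", "count_b"],
    ).to_csv(os.path.join(outdir, "conserved_mirnas.tsv"), sep="\t", index=False)

    # --- stage 4: isomiRs, spectrum, seed edits ------------------------
    mature_by_id = {m.mature_id: m for m in matures}
    prec_by_id = {p.precursor_id: p for p in precursors}
    variants = []
    for tag in retained:
        mid = assignments.get(tag.sequence)
        if mid is None:
            continue
        mat = mature_by_id[mid]
        prec = prec_by_id.get(mat.precursor_id)
        if prec is None:
            continue
        variants.append(iso.classify_isomir(tag, mat, prec))
    unassigned = [t for t in retained if t.sequence not in assignments]
    seed_calls = iso.detect_seed_edits(unassigned, matures)
    spectrum = iso.substitution_spectrum(variants, seed_calls)
    spectrum.to_csv(os.path.join(outdir, "substitution_spectrum.tsv"), sep="\t")
    edit_hist = iso.edit_position_histogram(seed_calls)
    class_counts: Dict[str, int] = {}
    for var in variants:
        for cls in sorted(var.classes):
            class_counts[cls] = class_counts.get(cls, 0) + 1
    report["isomir"] = {
        "n_variants": len(variants),
        "class_counts": class_counts,
        "n_seed_edit_calls": len(seed_calls),
        "edit_position_histogram": {int(k): int(v) for k, v in edit_hist.items()},
        "spectrum_pooled": {
            str(k): float(v) for k, v in spectrum["fraction"].items()
        },
    }

    # --- stage 5: novel prediction -------------------------------------
    novel = []
    if genome:
        called = {c.tag.sequence for c in seed_calls}
        candidates_tags = [t for t in unassigned if t.sequence not in called]
        hits = ann.map_to_genome(candidates_tags, genome, config.genome_max_mismatch)
        engine = get_fold_engine(config.fold_engine)
        tag_counts = {t.sequence: t.total for t in tags}
        novel = cat.predict_novel(
            hits,
            genome,
            engine,
            tag_counts=tag_counts,
            flank_proximal=config.flank_proximal,
            flank_distal=config.flank_distal,
            mfe_ceiling=config.mfe_ceiling,
        )
        write_bed6(
            os.path.join(outdir, "novel_candidates.bed"),
            [
                (c.chrom, c.start, c.start + len(c.mature_sequence),
                 f"novel-{i + 1}", c.mfe, c.strand)
                for i, c in enumerate(novel)
            ],
        )
        write_fasta(
            os.path.join(outdir, "novel_precursors.fasta"),
            [(f"novel-{i + 1}", c.precursor_sequence) for i, c in enumerate(novel)],
        )
    report["novel"] = {
        "n_candidates": len(novel),
        "loci": [
            {"chrom": c.chrom, "start": int(c.start), "strand": c.strand,
             "mfe": float(c.mfe)}
            for c in novel
        ],
    }

    # --- stage 6: differential expression ------------------------------
    de_table = de_mod.call_differential(
        [(r.mature_id, r.count_a, r.count_b) for r in mirna_records],
        n1=n1,
        n2=n2,
        fc_threshold=config.fc_threshold,
        alpha=config.alpha,
    )
    de_table.to_csv(
        os.path.join(outdir, "differential_expression.tsv"), sep="\t", index=False
    )
    report["differential_expression"] = {
        "n_tested": int(len(de_table)),
        "n_significant": int(de_table["significant"].sum()) if len(de_table) else 0,
        "n_up_in_A": int((de_table["direction"] == "up_in_A").sum())
        if len(de_table)
        else 0,
        "n_up_in_B": int((de_table["direction"] == "up_in_B").sum())
        if len(de_table)
        else 0,
    }

    # --- stage 7: target prediction for significant miRNAs -------------
    target_rows = []
    if transcripts and len(de_table):
        engine = tg.get_duplex_engine(config.duplex_engine)
        significant = de_table[de_table["significant"]]
        for _, row in significant.iterrows():
            rec = next(
                (r for r in mirna_records if r.mature_id == row["mirna_id"]), None
            )
            if rec is None:
                continue
            for dup, rep in tg.scan_targets(
                rec.mature_id, rec.sequence, transcripts, engine
            ):
                target_rows.append(
                    (dup.mirna_id, dup.transcript_id, dup.site_start,
                     dup.site_end, dup.mismatch_score, dup.mfe,
                     rep.values["mfe_ratio"])
                )
    pd.DataFrame(
        target_rows,
        columns=["mirna_id", "transcript_id", "start", "end",
                 "mismatch_score", "mfe", "mfe_ratio"],
    ).to_csv(os.path.join(outdir, "targets.tsv"), sep="\t", index=False)
    report["targets"] = {"n_sites": len(target_rows)}

    report["checksum"] = report_checksum(
        {k: v for k, v in report.items() if k != "config"}
    )
    with open(os.path.join(outdir, "report.json"), "w") as out:
        json.dump(_round(report), out, indent=2, sort_keys=True)
    return report
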