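"""File interfaces: per-sample VCF, AIRR-style clonotype TSV, expression CSV,
newick trees, and the ground-truth manifest."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import pysam
import yaml

from .datatypes import MutationRecord
from .synthetic.cohort import CaseData, SyntheticCohort

AIRR_COLUMNS = ["sample_id", "chain", "v_call", "j_call", "cdr3_nt", "cdr3_aa", "duplicate_count"]


def write_sample_vcf(
    path, case: CaseData, sample_id: str, contig_lengths: dict[str, int]
) -> None:
    """Write one metastasis's mutations as a single-sample VCF v4.2.

    INFO carries GENE/EFFECT/TNC; FORMAT carries DP and AD (ref, alt reads).
    Only mutations present in the sample are emitted.
    """
    header = pysam.VariantHeader()
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.info.add("EFFECT", 1, "String", "Protein effect class")
    header.info.add("TNC", 1, "String", "Reference-strand trinucleotide context")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.add_sample(sample_id)
    present = case.presence_true[sample_id]
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for m in case.mutations:
            if not present[m.mutation_id]:
                continue
            depth = int(case.depth.at[m.mutation_id, sample_id])
            alt = int(case.alt_reads.at[m.mutation_id, sample_id])
            rec = vcf.new_record(
                contig=m.chrom,
                start=m.pos - 1,
                alleles=(m.ref, m.alt),
                id=m.mutation_id,
            )
            rec.info["GENE"] = m.gene
            rec.info["EFFECT"] = m.effect
            rec.info["TNC"] = m.trinucleotide_context
            rec.samples[sample_id]["DP"] = depth
            rec.samples[sample_id]["AD"] = (max(depth - alt, 0), alt)
            vcf.write(rec)


def read_sample_vcf(path) -> list[tuple[MutationRecord, int, int]]:
    """Read a VCF written by :func:`write_sample_vcf`; returns (record, depth, alt)."""
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        sample = list(vcf.header.samples)[0]
        case_id = Path(str(path)).stem.split("-")[0]
        for rec in vcf:
            fmt = rec.samples[sample]
            m = MutationRecord(
                case_id=case_id,
                mutation_id=rec.id,
                chrom=rec.contig,
                pos=rec.pos,
                ref=rec.ref,
                alt=rec.alts[0],
                gene=rec.info["GENE"],
                effect=rec.info["EFFECT"],
                trinucleotide_context=rec.info["TNC"],
            )
            out.append((m, int(fmt["DP"]), int(fmt["AD"][1])))
    return out


def write_clonotypes_tsv(path, clonotypes: pd.DataFrame) -> None:
    clonotypes[AIRR_COLUMNS].to_csv(path, sep="\t", index=False)


def read_clonotypes_tsv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = set(AIRR_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"clonotype TSV lacks columns {sorted(missing)}")
    return frame


def write_cohort(cohort: SyntheticCohort, outdir) -> Path:
    """Serialize a cohort: VCFs, clonotype TSVs, expression CSV, trees, manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs = {name: len(g) for name, g in cohort.genome.genes.items()}
    for cid, case in cohort.cases.items():
        case_dir = outdir / cid
        case_dir.mkdir(exist_ok=True)
        for sid in case.sample_ids:
            write_sample_vcf(case_dir / f"{sid}.vcf", case, sid, contigs)
        write_clonotypes_tsv(case_dir / "clonotypes.tsv", case.clonotypes)
        (case_dir / "tree.nwk").write_text(case.tree_newick + "\n")
        case.hla_table.to_csv(case_dir / "hla.tsv", sep="\t", index=False)
    cohort.expression.to_csv(outdir / "expression_tpm.csv")
    cohort.reference_catalog.to_frame().to_csv(outdir / "reference_catalog.tsv", sep="\t")
    cohort.signature_catalog.to_csv(outdir / "signature_catalog.csv")
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(cohort.manifest(), fh, sort_keys=True)
    return outdir


def write_json(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    try:
        import numpy as np

        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON serializable: {type(obj)}")
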