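"""Readers and writers for the plain-text interchange formats.

FASTA proteomes (Biopython), mutation TSVs (case_id, protein_id, position,
ref_aa, alt_aa; 1-based), genotype TSV/JSON (A1..C2, DRB1_1, DRB1_2), and
peptide-ic50 training TSVs.
"""

from __future__ import annotations

import json
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .binding_model import TrainingExample
from .motif_core import Mutation, ProteinRecord
from .synthetic_data import GENOTYPE_COLUMNS

MUTATION_COLUMNS = ("case_id", "protein_id", "position", "ref_aa", "alt_aa")


def read_fasta(path) -> list[ProteinRecord]:
    """Proteome reader; protein_id = first whitespace-delimited token."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in seen:
            raise ValueError(f"duplicate protein_id {pid!r} in {path}")
        seen.add(pid)
        records.append(ProteinRecord(pid, str(rec.seq).upper()))
    return records


def write_fasta(proteins: Sequence[ProteinRecord], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(p.sequence), id=p.protein_id, description="") for p in proteins],
        str(path),
        "fasta",
    )


def read_mutations(path) -> list[Mutation]:
    df = pd.read_csv(path, sep="\t", dtype={"position": int})
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table missing columns {missing}")
    return [
        Mutation(str(r.case_id), str(r.protein_id), int(r.position),
                 str(r.ref_aa), str(r.alt_aa))
        for r in df.itertuples(index=False)
    ]


def write_mutations(mutations: Sequence[Mutation], path) -> None:
    pd.DataFrame(
        [(m.case_id, m.protein_id, m.position, m.ref_aa, m.alt_aa) for m in mutations],
        columns=list(MUTATION_COLUMNS),
    ).to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> pd.DataFrame:
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            df = pd.DataFrame(json.load(fh))
    else:
        df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("case_id", *GENOTYPE_COLUMNS) if c not in df.columns]
    if missing:
        raise ValueError(f"genotype table missing columns {missing}")
    return df


def write_genotypes(genotypes: pd.DataFrame, path) -> None:
    genotypes.to_csv(path, sep="\t", index=False)


def read_training_set(path) -> list[TrainingExample]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("allele", "peptide", "ic50_nM") if c not in df.columns]
    if missing:
        raise ValueError(f"training table missing columns {missing}")
    return [
        TrainingExample(str(r.allele), str(r.peptide), float(r.ic50_nM))
        for r in df.itertuples(index=False)
    ]


def write_training_set(examples: Sequence[TrainingExample], path) -> None:
    pd.DataFrame(
        [(e.allele, e.peptide, e.ic50_nM) for e in examples],
        columns=["allele", "peptide", "ic50_nM"],
    ).to_csv(path, sep="\t", index=False)
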