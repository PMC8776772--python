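"""File formats: FASTA protein databases and TSV tables.

FASTA headers carry the taxon and annotation metadata the mapping stage
needs: ``>prot00001 taxon=taxon1 annot="50S ribosomal protein L2"``.
All tables are tab-separated UTF-8 with a header row and '.' decimals.
"""
from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .digestion import ProteinRecord
from .synthetic import CommunityConfig, ReplicateCultureSet, TruthTable

_HEADER_RE = re.compile(r'taxon=(?P<taxon>\S+)\s+annot="(?P<annot>[^"]*)"')


def write_fasta(proteins: Sequence[ProteinRecord], path) -> None:
    records = []
    for p in proteins:
        annot = "; ".join(p.annotations)
        rec = SeqRecord(Seq(p.sequence), id=p.id,
                        description=f'taxon={p.taxon} annot="{annot}"')
        records.append(rec)
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[ProteinRecord]:
    proteins = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _HEADER_RE.search(rec.description)
        if not m:
            raise ValueError(
                f"FASTA header {rec.description!r} lacks taxon=/annot= fields"
            )
        annotations = tuple(
            a.strip() for a in m.group("annot").split(";") if a.strip()
        )
        proteins.append(ProteinRecord(id=rec.id, taxon=m.group("taxon"),
                                      sequence=str(rec.seq),
                                      annotations=annotations))
    return proteins


def write_tsv(frame: pd.DataFrame, path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_truth(truth: TruthTable, proteins_path, abundance_path) -> None:
    write_tsv(truth.proteins.reset_index().rename(columns={"index": "id"}),
              proteins_path)
    long = (truth.abundance.reset_index(names="id")
            .melt(id_vars="id", var_name="timepoint", value_name="abundance"))
    write_tsv(long, abundance_path)


def read_truth(proteins_path, abundance_path,
               config: CommunityConfig) -> TruthTable:
    proteins = read_tsv(proteins_path).set_index("id")
    long = read_tsv(abundance_path)
    abundance = long.pivot(index="id", columns="timepoint", values="abundance")
    abundance.columns = [int(c) for c in abundance.columns]
    abundance = abundance.loc[proteins.index]
    return TruthTable(proteins=proteins, abundance=abundance, config=config)


def write_cultures(cultures: ReplicateCultureSet, path) -> None:
    write_tsv(cultures.to_frame(), path)


def read_cultures(path) -> ReplicateCultureSet:
    return ReplicateCultureSet.from_frame(read_tsv(path))


def write_peptide_map(pepmap: pd.DataFrame, path) -> None:
    out = pepmap.copy()
    for col in ("parents", "taxa", "pools"):
        out[col] = out[col].map(lambda t: ";".join(t))
    out.index.name = "peptide"
    write_tsv(out.reset_index(), path)


def read_peptide_map(path) -> pd.DataFrame:
    df = read_tsv(path).set_index("peptide")
    for col in ("parents", "taxa", "pools"):
        df[col] = df[col].map(lambda s: tuple(str(s).split(";")))
    df["taxon"] = [t[0] if len(t) == 1 else None for t in df["taxa"]]
    df["pool"] = [p[0] if len(p) == 1 else None for p in df["pools"]]
    return df
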