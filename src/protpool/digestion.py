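"""In-silico tryptic digestion and peptide-to-taxon mapping.

Peptides are the observational unit of shotgun metaproteomics: a peptide can
only be attributed to a taxon (or to a functional protein pool) if every
database protein containing it belongs to that taxon (pool).  This module
digests a protein database, deduplicates the resulting peptides, and records
for each peptide the set of parent proteins, taxa and coarse-grained pools,
together with taxon-/pool-uniqueness flags and mass-to-charge features.

Coarse-grained pool assignment is keyword based and greedy: a protein joins a
pool if at least one of its free-text annotations matches the pool's keyword
family (case-insensitive substring match).  The photosynthetic family covers
light-harvesting, chlorophyll a-b binding, photosystem, plastocyanin and
flavodoxin annotations; the ribosomal family is the prefix ``ribosom`` minus
an exclusion list for ribosome synthesis/biogenesis terms.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _pymass

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS)

#: charge states modeled for precursor m/z
CHARGES = (2, 3)

RIBOSOMAL_POOL = "ribosomal"
PHOTOSYNTHETIC_POOL = "photosynthetic"
NO_POOL = "none"

PHOTOSYNTHETIC_KEYWORDS = (
    "light harvesting",
    "chlorophyll a-b binding",
    "photosystem",
    "plastocyanin",
    "flavodoxin",
)

RIBOSOMAL_PREFIX = "ribosom"

#: annotation substrings that disqualify a "ribosom*" match (ribosome
#: synthesis/biogenesis machinery is not part of the ribosomal pool)
RIBOSOMAL_EXCLUSIONS = (
    "ribosome biogenesis",
    "ribosomal rna",
    "ribosome synthesis",
    "ribosomal synthesis",
    "rrna",
)


class DigestionError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinRecord:
    """A database protein with taxon and annotation metadata.

    Parameters
    ----------
    id : str
        Unique identifier within a database.
    taxon : str
        Coarse taxonomic group label.
    sequence : str
        Amino-acid sequence over the 20 standard residues.
    annotations : tuple of str
        Free-text functional annotation strings.
    pool : str or None
        Coarse-grained pool label; if ``None`` it is derived from the
        annotations via :func:`assign_coarse_grains`.
    """

    id: str
    taxon: str
    sequence: str
    annotations: tuple = ()
    pool: str | None = None

    def __post_init__(self):
        if not self.sequence:
            raise DigestionError(f"protein {self.id!r} has an empty sequence")
        bad = set(self.sequence) - _VALID_RESIDUES
        if bad:
            raise DigestionError(
                f"protein {self.id!r} contains invalid residues: {sorted(bad)}"
            )
        if isinstance(self.annotations, str):
            object.__setattr__(self, "annotations", (self.annotations,))
        else:
            object.__setattr__(self, "annotations", tuple(self.annotations))


@dataclass(frozen=True)
class PeptideRecord:
    """A tryptic peptide mapped back to its parent proteins."""

    sequence: str
    parents: tuple
    taxa: tuple
    pools: tuple
    taxon_unique: bool
    pool_unique: bool
    monoisotopic_mass: float | None = None
    mz_by_charge: dict | None = None


def cleavage_sites(sequence: str) -> list[int]:
    """Positions after which trypsin cleaves (C-terminal to K/R, not before P)."""
    return [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest_protein(
    protein: ProteinRecord | str,
    missed_cleavages: int = 1,
    length_bounds: tuple[int, int] = (6, 40),
) -> list[str]:
    """Tryptic digest of one protein.

    Cleaves C-terminal to K or R except when the next residue is P, and
    returns all fragments with up to ``missed_cleavages`` internal sites,
    filtered to ``length_bounds``, ordered by position in the protein (and,
    at equal start, by increasing number of missed cleavages).
    """
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    if not seq:
        raise DigestionError("cannot digest an empty sequence")
    if not 0 <= missed_cleavages <= 2:
        raise DigestionError("missed_cleavages must be in [0, 2]")
    lo, hi = length_bounds
    bounds = [0] + cleavage_sites(seq) + [len(seq)]
    peptides = []
    for i in range(len(bounds) - 1):
        for mc in range(missed_cleavages + 1):
            j = i + 1 + mc
            if j >= len(bounds):
                break
            pep = seq[bounds[i]: bounds[j]]
            if lo <= len(pep) <= hi:
                peptides.append(pep)
    return peptides


def _matches_ribosomal(annotation: str) -> bool:
    a = annotation.lower()
    if RIBOSOMAL_PREFIX not in a:
        return False
    return not any(term in a for term in RIBOSOMAL_EXCLUSIONS)


def _matches_photosynthetic(annotation: str) -> bool:
    a = annotation.lower()
    return any(key in a for key in PHOTOSYNTHETIC_KEYWORDS)


def assign_coarse_grains(annotations: Iterable[str]) -> str:
    """Greedy keyword assignment of a protein to a coarse-grained pool.

    Returns ``"ribosomal"``, ``"photosynthetic"`` or ``"none"``.  A protein
    matching both keyword families is conservatively assigned ``"none"`` and
    a warning is logged (conflicts would otherwise require manual curation).
    """
    annotations = list(annotations)
    ribo = any(_matches_ribosomal(a) for a in annotations)
    photo = any(_matches_photosynthetic(a) for a in annotations)
    if ribo and photo:
        logger.warning(
            "annotations %r match both ribosomal and photosynthetic keyword "
            "families; assigning pool 'none'",
            annotations,
        )
        return NO_POOL
    if ribo:
        return RIBOSOMAL_POOL
    if photo:
        return PHOTOSYNTHETIC_POOL
    return NO_POOL


def peptide_mz(monoisotopic_mass: float, charge: int) -> float:
    return (monoisotopic_mass + charge * _pymass.calculate_mass(formula="H+")) / charge


def build_peptide_map(
    proteins: Sequence[ProteinRecord],
    missed_cleavages: int = 1,
    length_bounds: tuple[int, int] = (6, 40),
    compute_masses: bool = True,
) -> pd.DataFrame:
    """Digest a protein database into a deduplicated peptide map.

    Parameters
    ----------
    proteins : sequence of ProteinRecord
    missed_cleavages, length_bounds
        Digestion settings (defaults: 1 missed cleavage, 6-40 residues).
    compute_masses : bool
        Whether to compute monoisotopic masses and m/z for charges 2 and 3
        (skip for large simulations where only mapping is needed).

    Returns
    -------
    pandas.DataFrame
        Indexed by peptide sequence (lexicographic order) with columns
        ``parents``, ``taxa``, ``pools`` (sorted tuples), ``n_parents``,
        ``taxon_unique``, ``pool_unique``, ``taxon``, ``pool`` (the single
        label when unique, else ``None``) and, if requested, ``mass``,
        ``mz2``, ``mz3``.
    """
    if not proteins:
        raise DigestionError("protein database is empty")
    ids = [p.id for p in proteins]
    if len(set(ids)) != len(ids):
        raise DigestionError("protein ids are not unique within the database")

    pep_rows: list[tuple[str, str, str, str]] = []
    for prot in proteins:
        pool = prot.pool if prot.pool is not None else assign_coarse_grains(prot.annotations)
        for pep in set(digest_protein(prot, missed_cleavages, length_bounds)):
            pep_rows.append((pep, prot.id, prot.taxon, pool))

    raw = pd.DataFrame(pep_rows, columns=["peptide", "parent", "taxon", "pool"])
    grouped = raw.groupby("peptide", sort=True)
    df = pd.DataFrame(
        {
            "parents": grouped["parent"].agg(lambda s: tuple(sorted(set(s)))),
            "taxa": grouped["taxon"].agg(lambda s: tuple(sorted(set(s)))),
            "pools": grouped["pool"].agg(lambda s: tuple(sorted(set(s)))),
        }
    )
    df["n_parents"] = df["parents"].map(len)
    df["taxon_unique"] = df["taxa"].map(len) == 1
    df["pool_unique"] = df["pools"].map(len) == 1
    df["taxon"] = [t[0] if len(t) == 1 else None for t in df["taxa"]]
    df["pool"] = [p[0] if len(p) == 1 else None for p in df["pools"]]

    if compute_masses:
        masses = np.array([_pymass.fast_mass(p) for p in df.index], dtype=float)
        df["mass"] = masses
        for z in CHARGES:
            df[f"mz{z}"] = (masses + z * 1.00727646688) / z
    return df


def peptide_records(pepmap: pd.DataFrame) -> Iterable[PeptideRecord]:
    """Yield :class:`PeptideRecord` views of a peptide-map frame."""
    has_mass = "mass" in pepmap.columns
    for seq, row in pepmap.iterrows():
        yield PeptideRecord(
            sequence=seq,
            parents=row["parents"],
            taxa=row["taxa"],
            pools=row["pools"],
            taxon_unique=bool(row["taxon_unique"]),
            pool_unique=bool(row["pool_unique"]),
            monoisotopic_mass=float(row["mass"]) if has_mass else None,
            mz_by_charge={z: float(row[f"mz{z}"]) for z in CHARGES} if has_mass else None,
        )
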