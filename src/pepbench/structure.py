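"""Tertiary-structure approximation by clipping database hits.

Structure-based encodings need per-residue 3D coordinates, but predicting
structures for thousands of peptides is impractical.  Instead, each query
sequence is searched against a database built from structure files (so
every database record has known coordinates); the best hit — the one with
the lowest e-value — is clipped to the matched residue range and returned
as the query's approximate structure.  Queries without a hit are omitted
and reported, so downstream encoding steps can intersect record sets.

The search engine is pluggable: :class:`SubstringBackend` is a
deterministic exact-substring engine used in tests and small runs;
:class:`BlastBackend` shells out to an external BLAST+ installation for
real searches.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
from Bio.PDB import PDBParser

from pepbench.datasets import PeptideDataset
from pepbench.errors import BackendError, EmptyInputError, ValidationError

logger = logging.getLogger(__name__)

_THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F", "GLY": "G",
    "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L", "MET": "M", "ASN": "N",
    "PRO": "P", "GLN": "Q", "ARG": "R", "SER": "S", "THR": "T", "VAL": "V",
    "TRP": "W", "TYR": "Y",
}


@dataclass
class ChainRecord:
    """One database record: a structure chain with sequence and residue atoms."""

    id: str  # "<entry>_<chain>"
    sequence: str
    residues: list[dict]  # per residue: {"name": str, "atoms": {atom: xyz}}


@dataclass
class StructureDatabase:
    """Sequence database over structure chains."""

    records: dict[str, ChainRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)


def build_structure_db(structure_files: Sequence[str | Path]) -> StructureDatabase:
    """Parse PDB files into a chain-level sequence database.

    One record per chain, id ``<filestem>_<chain>``.  Unparseable files
    are logged and skipped; an empty database is fatal.  Residues are kept
    in author order (insertion-code order as stored in the file) and only
    the 20 standard amino acids contribute to the extracted sequence.
    """
    if not structure_files:
        raise EmptyInputError("no structure files given")
    parser = PDBParser(QUIET=True)
    db = StructureDatabase()
    for path in structure_files:
        path = Path(path)
        try:
            model = next(parser.get_structure(path.stem, str(path)).get_models())
        except Exception as exc:
            logger.warning("skipping unparseable structure %s (%s)", path, exc)
            continue
        for chain in model:
            residues = []
            letters = []
            for res in chain:
                name = res.get_resname().strip()
                if name not in _THREE_TO_ONE:
                    continue
                atoms = {a.get_name(): np.asarray(a.get_coord(), dtype=float)
                         for a in res.get_atoms()}
                residues.append({"name": _THREE_TO_ONE[name], "atoms": atoms})
                letters.append(_THREE_TO_ONE[name])
            if letters:
                rec_id = f"{path.stem}_{chain.id}"
                db.records[rec_id] = ChainRecord(rec_id, "".join(letters), residues)
    if not db.records:
        raise EmptyInputError("structure database is empty: no parseable chains")
    logger.info("structure database: %d chain record(s)", len(db))
    return db


@dataclass(frozen=True)
class StructureHit:
    """One search hit: matched ranges are 1-based inclusive and equal length."""

    query_id: str
    db_entry: str
    evalue: float
    identity: float
    query_range: tuple[int, int]
    db_range: tuple[int, int]
    mismatches: int = 0

    def __post_init__(self) -> None:
        qa, qb = self.query_range
        da, db_ = self.db_range
        if qa < 1 or da < 1 or qb < qa or db_ < da:
            raise ValidationError(f"hit for {self.query_id}: bad ranges")
        if qb - qa != db_ - da:
            raise ValidationError(f"hit for {self.query_id}: range lengths differ")
        if self.evalue < 0:
            raise ValidationError(f"hit for {self.query_id}: negative e-value")


class SearchBackend(Protocol):
    """Pluggable sequence-search engine over a structure database."""

    def search(self, query_id: str, query_seq: str, db: StructureDatabase) -> list[StructureHit]: ...


class SubstringBackend:
    """Deterministic mock engine: exact substring hits only.

    The pseudo e-value shrinks with match length and grows with database
    size, mimicking the qualitative behaviour of a real search: evalue =
    total_db_residues * 20^(-match_length).
    """

    def search(self, query_id: str, query_seq: str, db: StructureDatabase) -> list[StructureHit]:
        total = sum(len(r.sequence) for r in db.records.values())
        hits = []
        for rec in sorted(db.records.values(), key=lambda r: r.id):
            pos = rec.sequence.find(query_seq)
            if pos < 0:
                continue
            hits.append(
                StructureHit(
                    query_id=query_id,
                    db_entry=rec.id,
                    evalue=total * 20.0 ** (-len(query_seq)),
                    identity=1.0,
                    query_range=(1, len(query_seq)),
                    db_range=(pos + 1, pos + len(query_seq)),
                )
            )
        return hits


class BlastBackend:
    """Adapter around an external BLAST+ installation (makeblastdb + blastp).

    Requires the ``makeblastdb`` and ``blastp`` executables on PATH; uses
    the short-peptide task and tabular output.  Intended for real runs —
    tests use :class:`SubstringBackend`.
    """

    def __init__(self, evalue_cutoff: float = 10.0):
        self.evalue_cutoff = evalue_cutoff
        for tool in ("makeblastdb", "blastp"):
            if shutil.which(tool) is None:
                raise BackendError(f"{tool} not found on PATH")

    def search(self, query_id: str, query_seq: str, db: StructureDatabase) -> list[StructureHit]:
        with tempfile.TemporaryDirectory() as tmp:
            tmp = Path(tmp)
            fasta = tmp / "db.fasta"
            fasta.write_text(
                "".join(f">{r.id}\n{r.sequence}\n" for r in db.records.values())
            )
            query = tmp / "query.fasta"
            query.write_text(f">{query_id}\n{query_seq}\n")
            try:
                subprocess.run(
                    ["makeblastdb", "-in", str(fasta), "-dbtype", "prot"],
                    check=True, capture_output=True,
                )
                out = subprocess.run(
                    ["blastp", "-task", "blastp-short", "-query", str(query),
                     "-db", str(fasta), "-outfmt",
                     "6 sseqid evalue pident qstart qend sstart send mismatch",
                     "-evalue", str(self.evalue_cutoff)],
                    check=True, capture_output=True, text=True,
                ).stdout
            except subprocess.CalledProcessError as exc:
                raise BackendError(f"BLAST failed: {exc.stderr}") from exc
        hits = []
        for line in out.splitlines():
            sid, ev, pident, qs, qe, ss, se, mm = line.split("\t")
            if int(se) < int(ss):
                continue  # reverse matches cannot be clipped
            hits.append(
                StructureHit(
                    query_id=query_id, db_entry=sid, evalue=float(ev),
                    identity=float(pident) / 100.0,
                    query_range=(int(qs), int(qe)), db_range=(int(ss), int(se)),
                    mismatches=int(mm),
                )
            )
        return hits


@dataclass
class ClippedStructure:
    """Approximate structure: the matched residue range clipped from a hit."""

    query_id: str
    hit: StructureHit
    residues: list[dict]  # {"name": one-letter, "atoms": {atom: xyz}}

    @property
    def sequence(self) -> str:
        return "".join(r["name"] for r in self.residues)

    def to_pdb(self, path: str | Path) -> None:
        """Write the clip as a minimal PDB file (all atoms of matched residues)."""
        lines = []
        serial = 1
        for i, res in enumerate(self.residues, start=1):
            three = {v: k for k, v in _THREE_TO_ONE.items()}[res["name"]]
            for atom_name, xyz in res["atoms"].items():
                lines.append(
                    f"ATOM  {serial:5d} {atom_name:<4s}{three:>4s} A{i:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00\n"
                )
                serial += 1
        Path(path).write_text("".join(lines) + "END\n")


def _best_hit(hits: list[StructureHit]) -> StructureHit:
    # lowest e-value; ties -> higher identity, then lexicographic db id
    return min(hits, key=lambda h: (h.evalue, -h.identity, h.db_entry))


def approximate_structures(
    dataset: PeptideDataset,
    db: StructureDatabase,
    backend: SearchBackend | None = None,
) -> tuple[list[ClippedStructure], list[tuple[str, str]]]:
    """Approximate a structure for every query by clipping its best hit.

    Per query the hit with the lowest e-value wins (ties broken by higher
    identity, then database id); the matched database range is clipped
    from the hit's chain.  Queries without any hit, or whose clip cannot
    be validated, appear in the omitted list as (id, reason).  Always:
    len(clips) + len(omitted) == len(dataset).
    """
    backend = backend or SubstringBackend()
    clips: list[ClippedStructure] = []
    omitted: list[tuple[str, str]] = []
    for rec in dataset.records:
        try:
            hits = backend.search(rec.id, rec.sequence, db)
        except BackendError:
            raise
        except Exception as exc:
            raise BackendError(f"backend failed on {rec.id}: {exc}") from exc
        if not hits:
            omitted.append((rec.id, "no hit"))
            continue
        hit = _best_hit(hits)
        chain = db.records.get(hit.db_entry)
        if chain is None:
            omitted.append((rec.id, f"unknown db entry {hit.db_entry}"))
            continue
        a, b = hit.db_range
        if b > len(chain.residues):
            omitted.append((rec.id, "hit range outside chain"))
            continue
        residues = chain.residues[a - 1 : b]
        if any(not r["atoms"] for r in residues):
            omitted.append((rec.id, "residue without coordinates in clip"))
            continue
        clip = ClippedStructure(rec.id, hit, residues)
        qa, qb = hit.query_range
        matched_query = rec.sequence[qa - 1 : qb]
        if hit.mismatches == 0 and clip.sequence != matched_query:
            raise ValidationError(
                f"{rec.id}: clip sequence {clip.sequence!r} != matched query "
                f"subsequence {matched_query!r}"
            )
        clips.append(clip)
    assert len(clips) + len(omitted) == len(dataset)
    return clips, omitted


def write_omitted_csv(omitted: list[tuple[str, str]], path: str | Path) -> None:
    Path(path).write_text(
        "id,reason\n" + "".join(f"{i},{r}\n" for i, r in omitted)
    )
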