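"""Mining of mmCIF base-pair annotations and geometric cross-checking.

Archival mmCIF files record base pairing in the ``ndb_struct_na_base_pair``
category; its ``hbond_type_28`` token carries a Saenger-style class, with
"19"/"20" denoting canonical Watson-Crick G-C/A-T and "?" unknown.  This
module extracts those records, selects the annotated-noncanonical subset,
recomputes the pairing from coordinates and reports annotations that
contradict the geometry — in particular canonical Watson-Crick pairs wrongly
labelled as noncanonical, which turn out to be common in the archive.  All
other codes are treated as opaque noncanonical labels; the category's full
code dictionary is not re-interpreted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import pandas as pd

from .basepair import BasePair, PairParams, _hbonds_between, classify_pair, strand_orientation
from .step_geometry import DinucleotideStep, dissect_steps
from .structure_io import Nucleotide, Structure

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotatedPairRecord",
    "CrosscheckRow",
    "IncidenceTable",
    "CANONICAL_CODES",
    "BASE_COMBOS",
    "parse_na_base_pair",
    "select_noncanonical",
    "normalize_code",
    "steps_with_mismatch",
    "crosscheck",
    "incidence_table",
]

#: hbond_type_28 values denoting canonical Watson-Crick or unknown pairing
CANONICAL_CODES = {"19", "20", "?"}

#: the ten order-normalized base combinations
BASE_COMBOS = ("A-A", "A-C", "A-G", "A-T", "C-C", "C-G", "C-T", "G-G", "G-T", "T-T")


@dataclass
class AnnotatedPairRecord:
    structure_id: str
    chain1: str
    res1: int
    chain2: str
    res2: int
    hbond_type_28: str  # raw token, un-normalized

    @property
    def code(self) -> str:
        return normalize_code(self.hbond_type_28)

    @property
    def key(self) -> tuple:
        """Order-normalized identity, deduplicating i-j vs j-i listings."""
        a = (self.chain1, self.res1)
        b = (self.chain2, self.res2)
        return (self.structure_id,) + tuple(sorted((a, b)))


def normalize_code(token: str) -> str:
    """Trim and strip leading zeros from a numeric annotation token."""
    t = str(token).strip()
    if t.isdigit():
        t = t.lstrip("0") or "0"
    return t


_TAGS = ["i_auth_asym_id", "i_auth_seq_id", "j_auth_asym_id", "j_auth_seq_id", "hbond_type_28"]


def parse_na_base_pair(path) -> list[AnnotatedPairRecord]:
    """Extract ndb_struct_na_base_pair records from one mmCIF file.

    Files lacking the category yield an empty list (logged); a row whose
    residue numbers do not parse raises, naming the offending row.  Records
    listed in both i-j and j-i order are deduplicated.
    """
    path = Path(path)
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()
    table = block.find("_ndb_struct_na_base_pair.", _TAGS)
    structure_id = path.stem
    if len(table) == 0:
        logger.info("%s: no ndb_struct_na_base_pair category", path.name)
        return []
    records, seen = [], set()
    for irow, row in enumerate(table):
        try:
            rec = AnnotatedPairRecord(
                structure_id=structure_id,
                chain1=row[0], res1=int(row[1]),
                chain2=row[2], res2=int(row[3]),
                hbond_type_28=gemmi.cif.as_string(row[4]) or "?",
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"{path.name}: malformed ndb_struct_na_base_pair row {irow + 1}: {exc}"
            ) from exc
        if rec.key in seen:
            continue
        seen.add(rec.key)
        records.append(rec)
    return records


def select_noncanonical(records: list[AnnotatedPairRecord]) -> list[AnnotatedPairRecord]:
    """Keep records whose (normalized) code is not 19, 20 or ? (idempotent)."""
    return [r for r in records if r.code not in CANONICAL_CODES]


def _find_nucleotide(structure: Structure, chain: str, res: int) -> Nucleotide | None:
    for nt in structure.chains.get(chain, []):
        if nt.res_num == res:
            return nt
    return None


def steps_with_mismatch(structure: Structure,
                        records: list[AnnotatedPairRecord]) -> list[DinucleotideStep]:
    """Every dinucleotide step containing a nucleotide of a selected record.

    A mismatch in the middle of a chain contributes both flanking steps; at a
    terminus only the single existing step.  Steps are returned once each;
    records pointing at absent residues are skipped with a warning.
    """
    flagged: set[tuple[str, int]] = set()
    for rec in records:
        for chain, res in ((rec.chain1, rec.res1), (rec.chain2, rec.res2)):
            if _find_nucleotide(structure, chain, res) is None:
                logger.warning("%s: record references missing residue %s/%s; skipped",
                               rec.structure_id, chain, res)
                continue
            flagged.add((chain, res))
    out, seen = [], set()
    for chain_id, chain in structure.chains.items():
        for step in dissect_steps(chain):
            if ((chain_id, step.nt1.res_num) in flagged or
                    (chain_id, step.nt2.res_num) in flagged):
                if step.step_id not in seen:
                    seen.add(step.step_id)
                    out.append(step)
    return out


@dataclass
class CrosscheckRow:
    record: AnnotatedPairRecord
    verdict: str  # consistent | mislabeled-WC | unresolvable
    computed_saenger: int | None = None
    computed_canonical: bool | None = None
    combo: str | None = None
    orientation: str = "n/a"


def crosscheck(records: list[AnnotatedPairRecord], structure: Structure,
               params: PairParams = PairParams()) -> list[CrosscheckRow]:
    """Recompute each annotated pair from geometry and compare with its label.

    Verdicts: ``mislabeled-WC`` when the annotation claims noncanonical but
    the geometry is a canonical Watson-Crick pair; ``unresolvable`` when the
    two residues form no pair geometrically (absent residues, no hydrogen
    bonds); ``consistent`` otherwise.
    """
    rows = []
    for rec in records:
        nt1 = _find_nucleotide(structure, rec.chain1, rec.res1)
        nt2 = _find_nucleotide(structure, rec.chain2, rec.res2)
        if nt1 is None or nt2 is None:
            rows.append(CrosscheckRow(rec, "unresolvable"))
            continue
        hbonds = _hbonds_between(nt1, nt2, params)
        if len(hbonds) < 1:
            rows.append(CrosscheckRow(rec, "unresolvable"))
            continue
        pair = classify_pair(BasePair(nt1, nt2, hbonds))
        orientation = strand_orientation(pair, structure.chains)
        annotated_noncanonical = rec.code not in CANONICAL_CODES
        if annotated_noncanonical and pair.canonical:
            verdict = "mislabeled-WC"
        else:
            verdict = "consistent"
        rows.append(CrosscheckRow(rec, verdict, pair.saenger, pair.canonical,
                                  pair.combo, orientation))
    return rows


@dataclass
class IncidenceTable:
    """Counts of noncanonical base combinations by strand orientation."""

    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def add(self, combo: str, orientation: str, n: int = 1) -> None:
        combo = "-".join(sorted(combo.replace("–", "-").split("-")))
        if combo not in BASE_COMBOS:
            raise ValueError(f"unknown base combination {combo!r}")
        if orientation not in ("parallel", "antiparallel"):
            raise ValueError(f"unknown orientation {orientation!r}")
        key = (combo, orientation)
        self.counts[key] = self.counts.get(key, 0) + n

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        """Render with base combinations as columns, orientations as rows."""
        data = {
            combo: [self.counts.get((combo, "antiparallel"), 0),
                    self.counts.get((combo, "parallel"), 0)]
            for combo in BASE_COMBOS
        }
        return pd.DataFrame(data, index=["antiparallel", "parallel"])


def incidence_table(results) -> IncidenceTable:
    """Tabulate combo x orientation counts from crosscheck rows or (combo,
    orientation) tuples; rows without a resolvable orientation are skipped."""
    table = IncidenceTable()
    for item in results:
        if isinstance(item, CrosscheckRow):
            combo, orientation = item.combo, item.orientation
        else:
            combo, orientation = item
        if combo is None or orientation not in ("parallel", "antiparallel"):
            continue
        table.add(combo, orientation)
    return table
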