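"""Fusion-topology bookkeeping for the chimeric nucleases.

The nuclease domain (residues 446-576, 131 amino acids) is split into an
N-terminal piece of X residues and a C-terminal piece of Y residues; the
zinc-finger array is inserted between them.  "Reverse" constructs keep the
native order and are named NX-ZF-CY; "straight" constructs join the native
termini to the finger array and are named CY-ZF-NX.  The residues between
the two retained pieces are missing from the model, and the inactivating
mutations from the toxicity screen are checked against that gap: a
mutation site that falls in the gap marks an interaction the model cannot
maintain.
"""

from __future__ import annotations

import csv
import dataclasses
import importlib.resources
from typing import Iterable, Optional, Sequence

from .errors import AlphabetError, CompositionError, InputError, RangeError

NUCLEASE_FIRST = 446
NUCLEASE_LAST = 576
NUCLEASE_LEN = NUCLEASE_LAST - NUCLEASE_FIRST + 1  # 131

STRAIGHT = "straight"
REVERSE = "reverse"

#: Longest block shared by the two composite DNA sequences; the zinc
#: fingers' specific recognition site retained from the finger complex.
DEFAULT_ZF_SITE = "GAACTATGAGG"

#: Repeat schemes prolonging the specific site into the composite duplex
#: sequence.  Each part is either a (start, stop) slice of the site or a
#: literal spacer.  These defaults reproduce the two construct sequences.
DEFAULT_SCHEMES = {
    STRAIGHT: ((0, 11), "CA", (0, 5)),
    REVERSE: ((1, 11), "CA", (0, 11)),
}


@dataclasses.dataclass(frozen=True)
class FusionComposition:
    """Which nuclease residues an NX-ZF-CY (or CY-ZF-NX) model contains.

    ``n_len`` (X) N-terminal and ``c_len`` (Y) C-terminal nuclease residues
    are retained; X + Y must stay below 131 so a gap always exists.
    """

    orientation: str
    n_len: int
    c_len: int
    zf_sequence: str = ""
    linker_n: str = ""
    linker_c: str = ""
    _missing_override: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.orientation not in (STRAIGHT, REVERSE):
            raise CompositionError(f"unknown orientation {self.orientation!r}")
        if self.n_len < 0 or self.c_len < 0:
            raise CompositionError("X and Y must be non-negative")
        if self.n_len + self.c_len >= NUCLEASE_LEN:
            raise CompositionError(
                f"X + Y = {self.n_len + self.c_len} must be < {NUCLEASE_LEN}"
            )

    @classmethod
    def from_missing_range(
        cls,
        orientation: str,
        missing_first: int,
        missing_last: int,
        **kwargs,
    ) -> "FusionComposition":
        """Construct from an explicitly stated missing range.

        Published tables occasionally state a gap that is off by one from
        the (X, Y) arithmetic; this constructor reproduces the stated range
        verbatim instead of recomputing it.
        """
        if not (NUCLEASE_FIRST < missing_first <= missing_last < NUCLEASE_LAST):
            raise RangeError(
                f"missing range {missing_first}-{missing_last} outside "
                f"{NUCLEASE_FIRST}-{NUCLEASE_LAST}"
            )
        n_len = missing_first - NUCLEASE_FIRST
        c_len = NUCLEASE_LAST - missing_last
        return cls(
            orientation,
            n_len,
            c_len,
            _missing_override=(missing_first, missing_last),
            **kwargs,
        )


def model_name(c: FusionComposition) -> str:
    """Canonical model name: reverse NX-ZF-CY, straight CY-ZF-NX."""
    if c.orientation == REVERSE:
        return f"N{c.n_len}–ZF–C{c.c_len}"
    return f"C{c.c_len}–ZF–N{c.n_len}"


def parse_model_name(name: str) -> FusionComposition:
    """Inverse of :func:`model_name`; accepts '-' or en-dash separators."""
    parts = name.replace("–", "-").split("-")
    if len(parts) != 3 or parts[1].upper() != "ZF":
        raise InputError(f"cannot parse model name {name!r}")
    a, b = parts[0], parts[2]
    try:
        if a[0].upper() == "N" and b[0].upper() == "C":
            return FusionComposition(REVERSE, int(a[1:]), int(b[1:]))
        if a[0].upper() == "C" and b[0].upper() == "N":
            return FusionComposition(STRAIGHT, int(b[1:]), int(a[1:]))
    except ValueError:
        pass
    raise InputError(f"cannot parse model name {name!r}")


def retained_and_missing(
    c: FusionComposition,
) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int], int]:
    """(n_range, c_range, missing_range, missing_count) in author numbering.

    Ranges are inclusive (first, last); an empty retained piece is returned
    as ``(first, first - 1)``.
    """
    n_range = (NUCLEASE_FIRST, NUCLEASE_FIRST + c.n_len - 1)
    c_range = (NUCLEASE_LAST - c.c_len + 1, NUCLEASE_LAST)
    if c._missing_override is not None:
        missing = c._missing_override
    else:
        missing = (n_range[1] + 1, c_range[0] - 1)
    missing_count = missing[1] - missing[0] + 1
    return n_range, c_range, missing, missing_count


# ---------------------------------------------------------------------------
# Mutation records (toxicity screen)
# ---------------------------------------------------------------------------

MULTIPLICITIES = ("single", "double", "triple", "frameshift")


@dataclasses.dataclass(frozen=True)
class MutationRecord:
    """One mutated site from the screen of inactivated nuclease genes."""

    position: Optional[int]
    wt_res: str
    mut_res: str
    multiplicity: str
    partner_positions: tuple[int, ...] = ()
    note: str = ""

    def __post_init__(self) -> None:
        if self.multiplicity not in MULTIPLICITIES:
            raise InputError(f"unknown multiplicity {self.multiplicity!r}")
        if self.multiplicity != "frameshift":
            if self.position is None or not (
                NUCLEASE_FIRST <= self.position <= NUCLEASE_LAST
            ):
                raise RangeError(
                    f"mutation position {self.position} outside "
                    f"{NUCLEASE_FIRST}-{NUCLEASE_LAST}"
                )

    @property
    def label(self) -> str:
        return f"{self.wt_res}{self.position}"


def load_mutation_table(path: Optional[str] = None) -> list[MutationRecord]:
    """Load the packaged screen table (or a user CSV with the same columns).

    Columns: record, multiplicity, position, wt, mut, note.  Rows sharing a
    ``record`` id form one multi-site event; frameshift rows carry no
    position and are excluded from positional mapping.
    """
    if path is None:
        source = importlib.resources.files("colefuse.data") / "table1_mutations.csv"
        text = source.read_text()
        rows = list(csv.DictReader(text.splitlines()))
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))

    by_record: dict[str, list[dict]] = {}
    order: list[str] = []
    for row in rows:
        rid = row["record"]
        if rid not in by_record:
            by_record[rid] = []
            order.append(rid)
        by_record[rid].append(row)

    records: list[MutationRecord] = []
    for rid in order:
        group = by_record[rid]
        positions = [int(r["position"]) for r in group if r["position"]]
        for row in group:
            pos = int(row["position"]) if row["position"] else None
            partners = tuple(p for p in positions if p != pos)
            records.append(
                MutationRecord(
                    position=pos,
                    wt_res=row["wt"],
                    mut_res=row["mut"],
                    multiplicity=row["multiplicity"],
                    partner_positions=partners,
                    note=row.get("note", "") or "",
                )
            )
    return records


def map_mutations_to_model(
    c: FusionComposition, muts: Iterable[MutationRecord]
) -> dict[str, list[str]]:
    """Screen sites that a model cannot carry because they fall in its gap.

    A site is missing iff its position lies in the model's missing range;
    multi-site records report each missing member individually.  Returns
    ``{multiplicity: sorted unique labels}``; frameshift records (no
    position) are skipped.
    """
    _, _, missing, _ = retained_and_missing(c)
    out: dict[str, list[str]] = {m: [] for m in MULTIPLICITIES if m != "frameshift"}
    for rec in muts:
        if rec.multiplicity == "frameshift" or rec.position is None:
            continue
        if missing[0] <= rec.position <= missing[1]:
            if rec.label not in out[rec.multiplicity]:
                out[rec.multiplicity].append(rec.label)
    for key in out:
        out[key].sort(key=lambda s: (int(s[1:]), s))
    return out


# ---------------------------------------------------------------------------
# Sequence assembly
# ---------------------------------------------------------------------------


def build_composite_dna(
    zf_site: str = DEFAULT_ZF_SITE,
    orientation: str = STRAIGHT,
    scheme: Optional[Sequence] = None,
) -> str:
    """Prolong the finger recognition site into a composite duplex sequence.

    ``scheme`` is a sequence of parts, each either a (start, stop) slice of
    ``zf_site`` or a literal string; parts are concatenated in order.  The
    default schemes repeat the site around a two-base spacer and yield the
    18-base straight-construct and 23-base reverse-construct sequences.
    """
    if not zf_site:
        raise AlphabetError("zf_site must be non-empty")
    if set(zf_site.upper()) - set("ACGT"):
        raise AlphabetError(f"non-ACGT character in zf_site {zf_site!r}")
    if scheme is None:
        if orientation not in DEFAULT_SCHEMES:
            raise InputError(f"unknown orientation {orientation!r}")
        scheme = DEFAULT_SCHEMES[orientation]
    parts: list[str] = []
    for part in scheme:
        if isinstance(part, str):
            if set(part.upper()) - set("ACGT"):
                raise AlphabetError(f"non-ACGT literal {part!r} in scheme")
            parts.append(part.upper())
        else:
            start, stop = part
            parts.append(zf_site.upper()[start:stop])
    return "".join(parts)


def assemble_fusion_sequence(
    c: FusionComposition, ncole7_seq: str, zf_trim: int = 0
) -> str:
    """Assemble the chimera's amino-acid sequence from its parts.

    ``ncole7_seq`` is the 131-residue nuclease sequence indexed 446-576.
    ``zf_trim`` cuts the last one or two finger residues when the linker
    geometry requires it.  Reverse order: N-part, linker, fingers, linker,
    C-part; straight swaps the nuclease pieces.
    """
    if len(ncole7_seq) != NUCLEASE_LEN:
        raise InputError(
            f"nuclease sequence must have {NUCLEASE_LEN} residues, got {len(ncole7_seq)}"
        )
    if zf_trim < 0 or zf_trim > len(c.zf_sequence):
        raise InputError("zf_trim out of range")
    n_part = ncole7_seq[: c.n_len]
    c_part = ncole7_seq[NUCLEASE_LEN - c.c_len :] if c.c_len else ""
    zf = c.zf_sequence[: len(c.zf_sequence) - zf_trim]
    if c.orientation == REVERSE:
        return n_part + c.linker_n + zf + c.linker_c + c_part
    return c_part + c.linker_n + zf + c.linker_c + n_part
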