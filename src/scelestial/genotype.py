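"""Genotype matrix types and TSV I/O.

Single-cell variant calls are modeled as an m-loci x n-samples matrix whose
entries are unordered diploid genotypes over {A, C, G, T} — ten distinct
states — plus a missing-value sentinel written ``X/X``.  Binary 0/1 variant
matrices (reference/variant) are supported by coding 0 as A/A and 1 as C/C.

States are stored internally as small integer codes; unordered pairs are
normalized to alphabetical order (``T/A`` parses to the same state as
``A/T``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, List, TextIO, Union

import numpy as np

__all__ = [
    "STATE_TOKENS",
    "MISSING",
    "N_OBSERVED",
    "GenotypeMatrix",
    "CellSequence",
    "state_from_token",
    "state_to_token",
    "parse_genotype_table",
    "serialize_genotype_table",
    "ParseError",
    "DialectError",
]

_BASES = "ACGT"
#: canonical observed states, alphabetical unordered pairs; index = state code
STATE_TOKENS: tuple = tuple(
    f"{a}/{b}" for a, b in itertools.combinations_with_replacement(_BASES, 2)
)
N_OBSERVED = len(STATE_TOKENS)  # 10
#: integer code of the missing-value sentinel (token ``X/X``)
MISSING = N_OBSERVED  # 10
MISSING_TOKEN = "X/X"

_TOKEN_TO_CODE = {tok: i for i, tok in enumerate(STATE_TOKENS)}
# accept both orders of each pair
for _i, _tok in enumerate(STATE_TOKENS):
    _a, _b = _tok.split("/")
    _TOKEN_TO_CODE[f"{_b}/{_a}"] = _i
_TOKEN_TO_CODE[MISSING_TOKEN] = MISSING

#: accepted spellings of "missing" in the binary dialect
BINARY_MISSING_TOKENS = frozenset({"NA", "3", "X", "-"})
_BINARY_REF = _TOKEN_TO_CODE["A/A"]  # 0 codes as A/A
_BINARY_VAR = _TOKEN_TO_CODE["C/C"]  # 1 codes as C/C
#: state codes used by the binary (reference/variant) coding
REF_STATE = _BINARY_REF
VAR_STATE = _BINARY_VAR


class ParseError(ValueError):
    """Malformed genotype table (unknown token, ragged rows, ...)."""


class DialectError(ValueError):
    """Matrix cannot be represented in the requested dialect."""


def state_from_token(token: str) -> int:
    """Return the state code for a ``X/Y`` genotype token (order-insensitive)."""
    try:
        return _TOKEN_TO_CODE[token.strip().upper()]
    except KeyError:
        raise ParseError(f"unknown genotype token {token!r}") from None


def state_to_token(code: int) -> str:
    if code == MISSING:
        return MISSING_TOKEN
    return STATE_TOKENS[code]


@dataclass(frozen=True)
class CellSequence:
    """One sample's genotype vector (length m, state codes)."""

    sample_id: str
    states: np.ndarray  # int8, values in 0..10

    def __post_init__(self):
        object.__setattr__(self, "states", np.asarray(self.states, dtype=np.int8))

    def __len__(self) -> int:
        return len(self.states)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CellSequence)
            and self.sample_id == other.sample_id
            and np.array_equal(self.states, other.states)
        )

    def has_missing(self) -> bool:
        return bool(np.any(self.states == MISSING))


@dataclass
class GenotypeMatrix:
    """Loci x samples genotype matrix (loci are rows, samples are columns)."""

    loci_ids: List[str]
    sample_ids: List[str]
    states: np.ndarray = field(repr=False)  # (m, n) int8

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int8)
        m, n = self.shape
        if m < 1 or n < 1:
            raise ValueError("matrix must have at least one locus and one sample")
        if len(self.loci_ids) != m or len(self.sample_ids) != n:
            raise ValueError(
                f"label/grid mismatch: {len(self.loci_ids)} loci ids, "
                f"{len(self.sample_ids)} sample ids, grid {self.states.shape}"
            )
        if self.states.min() < 0 or self.states.max() > MISSING:
            raise ValueError("invalid state code in matrix")

    @property
    def shape(self):
        return self.states.shape

    @property
    def n_loci(self) -> int:
        return self.states.shape[0]

    @property
    def n_samples(self) -> int:
        return self.states.shape[1]

    def sequence(self, j: int) -> CellSequence:
        return CellSequence(self.sample_ids[j], self.states[:, j].copy())

    def sequences(self) -> List[CellSequence]:
        return [self.sequence(j) for j in range(self.n_samples)]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeMatrix)
            and self.loci_ids == other.loci_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.states, other.states)
        )

    @classmethod
    def from_sequences(cls, seqs: Iterable[CellSequence], loci_ids=None) -> "GenotypeMatrix":
        seqs = list(seqs)
        states = np.column_stack([s.states for s in seqs])
        if loci_ids is None:
            loci_ids = [f"locus{i}" for i in range(states.shape[0])]
        return cls(list(loci_ids), [s.sample_id for s in seqs], states)


def _parse_binary_cell(token: str, row: str, col: str) -> int:
    t = token.strip()
    if t == "0":
        return _BINARY_REF
    if t == "1":
        return _BINARY_VAR
    if t.upper() in BINARY_MISSING_TOKENS:
        return MISSING
    raise ParseError(f"unknown binary token {token!r} at locus {row!r}, sample {col!r}")


def parse_genotype_table(
    text: Union[str, TextIO], dialect: str = "tenstate"
) -> GenotypeMatrix:
    """Parse a tab-separated genotype table.

    The header row holds sample ids (its first field, the locus-column title,
    is ignored); the first column of each data row is the locus id.  The
    ``tenstate`` dialect expects ``X/Y`` tokens, the ``binary`` dialect
    expects 0 / 1 / a missing token (NA, 3, X or -), coded as A/A, C/C and
    X/X respectively.
    """
    if dialect not in ("tenstate", "binary"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if hasattr(text, "read"):
        text = text.read()
    lines = [ln for ln in text.splitlines() if ln.strip() != ""]
    if len(lines) < 2:
        raise ParseError("table needs a header row and at least one data row")
    header = lines[0].rstrip("\n").split("\t")
    sample_ids = [h.strip() for h in header[1:]]
    if not sample_ids:
        raise ParseError("header row holds no sample ids")
    n = len(sample_ids)
    loci_ids: List[str] = []
    rows: List[List[int]] = []
    for ln in lines[1:]:
        fields = ln.rstrip("\n").split("\t")
        locus = fields[0].strip()
        cells = fields[1:]
        if len(cells) != n:
            raise ParseError(
                f"ragged row for locus {locus!r}: {len(cells)} cells, expected {n}"
            )
        if dialect == "tenstate":
            row = []
            for sid, tok in zip(sample_ids, cells):
                try:
                    row.append(state_from_token(tok))
                except ParseError:
                    raise ParseError(
                        f"unknown genotype token {tok!r} at locus {locus!r}, sample {sid!r}"
                    ) from None
        else:
            row = [_parse_binary_cell(tok, locus, sid) for tok, sid in zip(cells, sample_ids)]
        loci_ids.append(locus)
        rows.append(row)
    return GenotypeMatrix(loci_ids, sample_ids, np.array(rows, dtype=np.int8))


def serialize_genotype_table(matrix: GenotypeMatrix, dialect: str = "tenstate") -> str:
    """Render a matrix back to TSV text; ``parse(serialize(M)) == M``."""
    if dialect not in ("tenstate", "binary"):
        raise ValueError(f"unknown dialect {dialect!r}")
    out = ["locus\t" + "\t".join(matrix.sample_ids)]
    if dialect == "binary":
        allowed = {_BINARY_REF: "0", _BINARY_VAR: "1", MISSING: "NA"}
        bad = set(np.unique(matrix.states)) - set(allowed)
        if bad:
            raise DialectError(
                "binary dialect only holds A/A, C/C and missing; matrix contains "
                + ", ".join(state_to_token(int(c)) for c in sorted(bad))
            )
        for locus, row in zip(matrix.loci_ids, matrix.states):
            out.append(locus + "\t" + "\t".join(allowed[int(c)] for c in row))
    else:
        for locus, row in zip(matrix.loci_ids, matrix.states):
            out.append(locus + "\t" + "\t".join(state_to_token(int(c)) for c in row))
    return "\n".join(out) + "\n"


def sequences_from_strings(strings: Iterable[str], ids: Iterable[str] = None) -> List[CellSequence]:
    """Build homozygous sequences from base strings, e.g. "CAC" -> C/C,A/A,C/C.

    ``X`` marks a missing locus.  Convenience for small worked examples.
    """
    strings = list(strings)
    if ids is None:
        ids = [f"cell{i}" for i in range(len(strings))]
    seqs = []
    for sid, s in zip(ids, strings):
        codes = [
            MISSING if ch.upper() == "X" else _TOKEN_TO_CODE[f"{ch.upper()}/{ch.upper()}"]
            for ch in s
        ]
        seqs.append(CellSequence(sid, np.array(codes, dtype=np.int8)))
    return seqs
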