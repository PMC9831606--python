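"""Bookkeeping for knottin peptide variants across optimization rounds.

The inhibitor cystine-knot (ICK) scaffold used here is the 30-residue
tarantula toxin ProTx-II, whose six cysteines sit at positions
2, 9, 15, 16, 21 and 25.  Optimization campaigns produce families of
named variants differing by a handful of substitutions, some of them
non-canonical residues (norArg, norLeu, 2,4-dimethyl-phenylalanine,
tert-butyl-cysteine).  This module represents variants over an extended
residue alphabet, parses the compact one-character alignment tables used
to summarize rounds, and diffs/patches variants with standard "Y1H"
mutation notation.  Residue numbering is 1-based throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from io import StringIO
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ResidueCode",
    "ExtendedRegistry",
    "DEFAULT_REGISTRY",
    "PeptideVariant",
    "Mutation",
    "MutationSet",
    "ParseError",
    "parse_variant_table",
    "load_reference_variants",
    "diff_variants",
    "apply_mutations",
    "validate_scaffold",
    "ScaffoldReport",
    "write_fasta",
    "read_fasta",
    "CANONICAL_AA",
]

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Cysteine positions of the ProTx-II ICK scaffold (1-based).
ICK_CYSTEINES = (2, 9, 15, 16, 21, 25)


class ParseError(ValueError):
    """Raised when a variant table, FASTA file, or mutation token is malformed."""


@dataclass(frozen=True)
class ResidueCode:
    """One residue identity: a canonical one-letter code or an extended code.

    Parameters
    ----------
    code:
        ``"A"``..``"Y"`` for canonical residues, or a registry code such
        as ``"norArg"`` for non-canonical ones.
    display_char:
        Single character used in compact alignment tables.  Canonical
        residues display as themselves; extended codes use letters that
        are not canonical amino-acid codes (e.g. norArg displays as "X").
    parent:
        For extended codes, the canonical residue they are derived from
        (used only for reporting).
    """

    code: str
    display_char: str
    parent: str | None = None

    def __post_init__(self) -> None:
        if len(self.display_char) != 1:
            raise ValueError(f"display_char must be a single character: {self.display_char!r}")
        if self.is_extended and self.display_char in CANONICAL_AA:
            raise ValueError(
                f"extended code {self.code!r} displays as canonical letter "
                f"{self.display_char!r}; it would be ambiguous in an alignment"
            )

    @property
    def is_extended(self) -> bool:
        return len(self.code) > 1

    def __str__(self) -> str:  # compact rendering
        return self.display_char if not self.is_extended else self.code


def _canonical(letter: str) -> ResidueCode:
    return ResidueCode(code=letter, display_char=letter)


CANONICAL_CODES = {aa: _canonical(aa) for aa in CANONICAL_AA}


class ExtendedRegistry:
    """Registry of non-canonical residue codes and their display characters.

    The defaults cover the four codes used in the ProTx-II campaign.
    Display characters are drawn from letters that are not canonical
    amino-acid codes, so a compact alignment row stays unambiguous.
    """

    def __init__(self, entries: Iterable[ResidueCode] = ()) -> None:
        self._by_code: dict[str, ResidueCode] = {}
        self._by_display: dict[str, ResidueCode] = {}
        for entry in entries:
            self.add(entry)

    def add(self, entry: ResidueCode) -> None:
        if not entry.is_extended:
            raise ValueError(f"registry holds extended codes only, got {entry.code!r}")
        if entry.display_char in self._by_display:
            raise ValueError(f"display char {entry.display_char!r} already registered")
        self._by_code[entry.code] = entry
        self._by_display[entry.display_char] = entry

    def by_code(self, code: str) -> ResidueCode:
        return self._by_code[code]

    def by_display(self, char: str) -> ResidueCode | None:
        return self._by_display.get(char)

    def codes(self) -> list[str]:
        return sorted(self._by_code)

    def resolve(self, token: str) -> ResidueCode:
        """Resolve a one-letter canonical code, display char, or extended code."""
        if token in CANONICAL_CODES:
            return CANONICAL_CODES[token]
        if token in self._by_code:
            return self._by_code[token]
        if len(token) == 1 and token in self._by_display:
            return self._by_display[token]
        raise ParseError(f"unknown residue token {token!r}")


DEFAULT_REGISTRY = ExtendedRegistry(
    [
        ResidueCode("norArg", "X", parent="R"),
        ResidueCode("norLeu", "J", parent="L"),
        # 2,4-dimethyl-phenylalanine
        ResidueCode("dmF", "Z", parent="F"),
        # tert-butyl-cysteine
        ResidueCode("tbC", "U", parent="C"),
    ]
)


@dataclass(frozen=True)
class PeptideVariant:
    """A named peptide variant: an ordered residue list with metadata.

    Residues are 1-based: ``variant[1]`` is the first residue.
    """

    name: str
    residues: tuple[ResidueCode, ...]
    c_terminal_amidated: bool = True
    parent: str | None = None

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, position: int) -> ResidueCode:
        if not 1 <= position <= len(self.residues):
            raise IndexError(f"position {position} outside 1..{len(self.residues)}")
        return self.residues[position - 1]

    @property
    def sequence(self) -> str:
        """Compact one-character sequence (extended codes as display chars)."""
        return "".join(r.display_char for r in self.residues)

    @property
    def bracketed_sequence(self) -> str:
        """Sequence with extended codes spelled out in square brackets."""
        return "".join(
            r.display_char if not r.is_extended else f"[{r.code}]" for r in self.residues
        )

    def cysteine_positions(self) -> tuple[int, ...]:
        return tuple(i for i, r in enumerate(self.residues, start=1) if r.code == "C")

    def extended_positions(self) -> tuple[int, ...]:
        return tuple(i for i, r in enumerate(self.residues, start=1) if r.is_extended)

    @classmethod
    def from_string(
        cls,
        name: str,
        sequence: str,
        registry: ExtendedRegistry = DEFAULT_REGISTRY,
        **kwargs,
    ) -> "PeptideVariant":
        """Build a variant from a compact or bracketed sequence string."""
        residues: list[ResidueCode] = []
        i = 0
        while i < len(sequence):
            ch = sequence[i]
            if ch == "[":
                end = sequence.find("]", i)
                if end < 0:
                    raise ParseError(f"unterminated bracket in sequence for {name!r}")
                residues.append(registry.resolve(sequence[i + 1 : end]))
                i = end + 1
            else:
                residues.append(registry.resolve(ch))
                i += 1
        return cls(name=name, residues=tuple(residues), **kwargs)


@dataclass(frozen=True)
class Mutation:
    """A single substitution ``from -> to`` at a 1-based position."""

    position: int
    from_res: ResidueCode
    to_res: ResidueCode

    def __post_init__(self) -> None:
        if self.from_res == self.to_res:
            raise ValueError(f"mutation at {self.position} does not change the residue")

    def __str__(self) -> str:
        return f"{self.from_res}{self.position}{self.to_res}"


_MUTATION_RE = re.compile(r"^([A-Za-z]+?)(\d+)([A-Za-z]+)$")


@dataclass(frozen=True)
class MutationSet:
    """An ordered (by position) set of substitutions."""

    mutations: tuple[Mutation, ...] = ()

    def __post_init__(self) -> None:
        positions = [m.position for m in self.mutations]
        if positions != sorted(positions):
            object.__setattr__(
                self, "mutations", tuple(sorted(self.mutations, key=lambda m: m.position))
            )
        if len(set(positions)) != len(positions):
            raise ValueError("duplicate positions in mutation set")

    def __len__(self) -> int:
        return len(self.mutations)

    def __iter__(self):
        return iter(self.mutations)

    def __str__(self) -> str:
        return ",".join(str(m) for m in self.mutations)

    @classmethod
    def from_string(
        cls, text: str, registry: ExtendedRegistry = DEFAULT_REGISTRY
    ) -> "MutationSet":
        """Parse a comma-separated mutation list such as ``"Y1H,R22norArg"``."""
        mutations = []
        for token in filter(None, (t.strip() for t in text.split(","))):
            m = _MUTATION_RE.match(token)
            if m is None:
                raise ParseError(f"cannot parse mutation token {token!r}")
            from_tok, pos, to_tok = m.groups()
            mutations.append(
                Mutation(int(pos), registry.resolve(from_tok), registry.resolve(to_tok))
            )
        return cls(tuple(mutations))


def parse_variant_table(
    source: str | Path,
    registry: ExtendedRegistry = DEFAULT_REGISTRY,
    sep: str = "\t",
    c_terminal_amidated: bool = True,
) -> list[PeptideVariant]:
    """Parse a round-summary alignment table into peptide variants.

    The table has a header row ``name, 1, 2, ..., L`` of residue numbers
    and one row per variant whose cells are single display characters.
    ``source`` may be the table text itself or a path.

    Raises
    ------
    ParseError
        On ragged rows (naming the offending row) or unknown display
        characters (naming the position).
    """
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)

    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError("empty variant table")
    header = lines[0].split(sep)
    try:
        numbering = [int(tok) for tok in header[1:]]
    except ValueError as exc:
        raise ParseError(f"header row must be residue numbers: {exc}") from None
    if numbering != list(range(1, len(numbering) + 1)):
        raise ParseError("header residue numbers must run 1..L")

    variants = []
    for line in lines[1:]:
        cells = line.split(sep)
        name, chars = cells[0].strip(), [c.strip() for c in cells[1:]]
        if len(chars) != len(numbering):
            raise ParseError(
                f"row {name!r} has {len(chars)} residue cells, expected {len(numbering)}"
            )
        residues = []
        for pos, ch in zip(numbering, chars):
            try:
                residues.append(registry.resolve(ch))
            except ParseError:
                raise ParseError(
                    f"row {name!r}: unknown display character {ch!r} at position {pos}"
                ) from None
        variants.append(
            PeptideVariant(
                name=name,
                residues=tuple(residues),
                c_terminal_amidated=c_terminal_amidated,
            )
        )
    return variants


def load_reference_variants() -> dict[str, PeptideVariant]:
    """Load the packaged round-summary table of the ProTx-II campaign.

    Returns the wild-type scaffold and the lead variant of each
    optimization round, keyed by name.
    """
    text = resources.files("knotopt.data").joinpath("variant_rounds.tsv").read_text()
    return {v.name: v for v in parse_variant_table(text)}


def diff_variants(a: PeptideVariant, b: PeptideVariant) -> MutationSet:
    """Positions where ``a`` and ``b`` differ, reported as a -> b."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {a.name} has {len(a)}, {b.name} has {len(b)}")
    muts = [
        Mutation(i, ra, rb)
        for i, (ra, rb) in enumerate(zip(a.residues, b.residues), start=1)
        if ra != rb
    ]
    return MutationSet(tuple(muts))


def apply_mutations(
    parent: PeptideVariant, mutations: MutationSet, name: str
) -> PeptideVariant:
    """Apply substitutions to ``parent``; each ``from`` residue must match.

    The ``from`` check guards against transcription drift between a
    narrative substitution list and the actual parent sequence.
    """
    residues = list(parent.residues)
    for m in mutations:
        if not 1 <= m.position <= len(residues):
            raise ValueError(f"position {m.position} outside 1..{len(residues)}")
        current = residues[m.position - 1]
        if current != m.from_res:
            raise ValueError(
                f"mutation {m} does not match parent {parent.name}: position "
                f"{m.position} is {current}, expected {m.from_res}"
            )
        residues[m.position - 1] = m.to_res
    return PeptideVariant(
        name=name,
        residues=tuple(residues),
        c_terminal_amidated=parent.c_terminal_amidated,
        parent=parent.name,
    )


@dataclass(frozen=True)
class ScaffoldReport:
    """Report-only integrity check of a variant against its scaffold."""

    length_ok: bool
    expected_length: int
    observed_length: int
    cysteines_ok: bool
    expected_cysteines: tuple[int, ...]
    observed_cysteines: tuple[int, ...]
    n_extended: int
    extended_positions: tuple[int, ...]

    @property
    def ok(self) -> bool:
        return self.length_ok and self.cysteines_ok


def validate_scaffold(v: PeptideVariant, scaffold: PeptideVariant) -> ScaffoldReport:
    """Check length and cysteine-position integrity against the scaffold.

    Disulfide connectivity is not validated -- only that the cysteines sit
    at the scaffold positions, since the knot's pairing is not part of the
    sequence record.
    """
    expected_cys = scaffold.cysteine_positions()
    observed_cys = v.cysteine_positions()
    return ScaffoldReport(
        length_ok=len(v) == len(scaffold),
        expected_length=len(scaffold),
        observed_length=len(v),
        cysteines_ok=observed_cys == expected_cys,
        expected_cysteines=expected_cys,
        observed_cysteines=observed_cys,
        n_extended=len(v.extended_positions()),
        extended_positions=v.extended_positions(),
    )


def write_fasta(variants: Sequence[PeptideVariant], path: str | Path | None = None) -> str:
    """Write variants as FASTA with extended codes in square brackets.

    No standard one-letter codes exist for the non-canonical residues, so
    sequences are written machine-readably as e.g. ``...R[norArg]LW...``.
    """
    out = StringIO()
    for v in variants:
        out.write(f">{v.name}\n{v.bracketed_sequence}\n")
    text = out.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def read_fasta(
    source: str | Path, registry: ExtendedRegistry = DEFAULT_REGISTRY
) -> list[PeptideVariant]:
    """Read bracketed-code FASTA written by :func:`write_fasta`."""
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)
    variants = []
    name: str | None = None
    seq_parts: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                variants.append(PeptideVariant.from_string(name, "".join(seq_parts), registry))
            name, seq_parts = line[1:].strip(), []
        else:
            if name is None:
                raise ParseError("sequence data before first FASTA header")
            seq_parts.append(line)
    if name is not None:
        variants.append(PeptideVariant.from_string(name, "".join(seq_parts), registry))
    return variants
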