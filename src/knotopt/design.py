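"""Post-processing of protein-design engine outputs.

The design engine (an external tool; only its outputs are consumed here)
emits a whitespace-delimited scorefile whose data lines start with a
``SCORE:`` token: a total energy, an interface binding energy (ddG) and
extra numeric columns per design, plus a trailing tag.  This module

* parses scorefiles into :class:`DesignSet` records,
* applies the two-stage selection cascade used in the campaign
  (keep the ``n_score`` lowest total-score designs, then among them the
  ``n_ddg`` lowest-ddG designs),
* builds position-weight matrices / consensus sequences / sequence
  logos from the selected designs, and
* reads, writes and derives per-position design-constraint files
  ("resfiles", with PIKAA / NATAA / NOTAA commands) -- in particular
  deriving NOTAA bans on acidic residues at lipid-facing positions from
  a fractional-contact profile.

Lower is better for both total score and ddG (standard energy
convention).  Ties are broken by tag lexicographic order so the cascade
is reproducible.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .peptides import CANONICAL_AA

__all__ = [
    "ScoreRecord",
    "DesignSet",
    "ScorefileError",
    "read_scorefile",
    "select_designs",
    "PWM",
    "build_pwm",
    "consensus",
    "plot_logo",
    "ResfileCommand",
    "ResfileSpec",
    "ResfileError",
    "parse_resfile",
    "write_resfile",
    "derive_constraints",
]


class ScorefileError(ValueError):
    pass


@dataclass(frozen=True)
class ScoreRecord:
    """One design: tag, energies, sequence, and any extra numeric columns."""

    tag: str
    total_score: float
    ddg: float
    sequence: str | None = None
    extras: Mapping[str, float] = field(default_factory=dict)


@dataclass
class DesignSet:
    """A collection of design records with provenance of how it was made."""

    records: list[ScoreRecord]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        tags = [r.tag for r in self.records]
        if len(set(tags)) != len(tags):
            dup = sorted({t for t in tags if tags.count(t) > 1})
            raise ScorefileError(f"duplicate design tags: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def tags(self) -> list[str]:
        return [r.tag for r in self.records]

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records if r.sequence is not None]


def read_scorefile(
    source: str | Path,
    ddg_column: str = "ddg",
    sequence_column: str = "sequence",
    sequences: Mapping[str, str] | None = None,
) -> DesignSet:
    """Parse a ``SCORE:``-dialect scorefile.

    The first ``SCORE:`` line is the header; it must contain
    ``total_score``, a ddG-like column (name configurable) and a trailing
    ``description`` tag column.  Sequences are attached from
    ``sequence_column`` if present, else from the ``sequences`` mapping
    keyed by tag.
    """
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
        text = Path(source).read_text()
    else:
        text = str(source)

    header: list[str] | None = None
    records: list[ScoreRecord] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith("SCORE:"):
            continue
        tokens = line.split()[1:]
        if header is None:
            header = tokens
            for required in ("total_score", ddg_column, "description"):
                if required not in header:
                    raise ScorefileError(f"scorefile header lacks column {required!r}")
            continue
        if len(tokens) != len(header):
            raise ScorefileError(
                f"line {lineno}: {len(tokens)} fields, header has {len(header)}"
            )
        row = dict(zip(header, tokens))
        tag = row.pop("description")
        try:
            total = float(row.pop("total_score"))
            ddg = float(row.pop(ddg_column))
        except ValueError as exc:
            raise ScorefileError(f"line {lineno}: non-numeric score field: {exc}") from None
        if not (math.isfinite(total) and math.isfinite(ddg)):
            raise ScorefileError(f"line {lineno}: non-finite score for {tag!r}")
        seq = row.pop(sequence_column, None)
        if seq is None and sequences is not None:
            seq = sequences.get(tag)
        extras = {}
        for k, v in row.items():
            try:
                extras[k] = float(v)
            except ValueError:
                extras[k] = v
        records.append(ScoreRecord(tag=tag, total_score=total, ddg=ddg, sequence=seq, extras=extras))

    if header is None:
        raise ScorefileError("no SCORE: header line found")
    lengths = {len(r.sequence) for r in records if r.sequence is not None}
    if len(lengths) > 1:
        raise ScorefileError(f"sequences of unequal length in scorefile: {sorted(lengths)}")
    return DesignSet(records=records, provenance=[f"read {len(records)} records"])


def select_designs(ds: DesignSet, n_score: int = 100, n_ddg: int = 20) -> DesignSet:
    """Two-stage cascade: lowest ``n_score`` by total score, then lowest
    ``n_ddg`` of those by ddG.  Ties break by tag; if the set is small,
    everything is returned (ordered)."""
    if not (n_score >= n_ddg >= 1):
        raise ValueError("need n_score >= n_ddg >= 1")
    stage1 = sorted(ds.records, key=lambda r: (r.total_score, r.tag))[:n_score]
    stage2 = sorted(stage1, key=lambda r: (r.ddg, r.tag))[:n_ddg]
    return DesignSet(
        records=stage2,
        provenance=ds.provenance
        + [
            f"stage 1: kept {len(stage1)} of {len(ds)} by total_score (n_score={n_score})",
            f"stage 2: kept {len(stage2)} of {len(stage1)} by ddg (n_ddg={n_ddg})",
        ],
    )


@dataclass
class PWM:
    """Position-weight matrix over a residue alphabet.

    ``freqs`` columns are exact count ratios summing to 1 per position.
    ``information_content`` is log2(|alphabet|) minus the Shannon entropy
    of the column, in bits (no small-sample correction by default).
    """

    freqs: pd.DataFrame  # index: 1-based position, columns: alphabet
    n_sequences: int

    @property
    def alphabet(self) -> str:
        return "".join(self.freqs.columns)

    @property
    def information_content(self) -> pd.Series:
        p = self.freqs.to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log2(p), 0.0)
        entropy = -plogp.sum(axis=1)
        return pd.Series(
            np.log2(len(self.freqs.columns)) - entropy, index=self.freqs.index, name="ic_bits"
        )

    def small_sample_corrected_ic(self) -> pd.Series:
        """IC with the small-sample correction used by some logo tools."""
        e_n = (len(self.freqs.columns) - 1) / (2 * math.log(2) * self.n_sequences)
        return (self.information_content - e_n).clip(lower=0.0)

    def to_csv(self, path: str | Path | None = None) -> str:
        text = self.freqs.to_csv(index_label="position")
        if path is not None:
            Path(path).write_text(text)
        return text


def build_pwm(sequences: Sequence[str], alphabet: str = CANONICAL_AA) -> PWM:
    """Column frequencies (exact count ratios) of equal-length sequences."""
    if len(sequences) == 0:
        raise ValueError("need at least one sequence")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"ragged sequences: lengths {sorted(lengths)}")
    length = lengths.pop()
    counts = np.zeros((length, len(alphabet)), dtype=int)
    index = {aa: j for j, aa in enumerate(alphabet)}
    for seq in sequences:
        for i, aa in enumerate(seq):
            if aa not in index:
                raise ValueError(f"residue {aa!r} not in alphabet")
            counts[i, index[aa]] += 1
    freqs = pd.DataFrame(
        counts / len(sequences), index=range(1, length + 1), columns=list(alphabet)
    )
    return PWM(freqs=freqs, n_sequences=len(sequences))


def consensus(pwm: PWM, tie_break: str = "alphabetical") -> str:
    """Per-position argmax sequence; ties break alphabetically.

    Note the campaign's own consensus combined the logo with expert
    choices (sometimes picking a lower-ranked residue); such overrides
    are manual inputs, not reproduced here.
    """
    if tie_break != "alphabetical":
        raise ValueError(f"unknown tie-break rule {tie_break!r}")
    # columns are iterated in alphabet order, so idxmax takes the
    # alphabetically first residue on ties as long as the alphabet is sorted;
    # sort explicitly to be safe.
    cols = sorted(pwm.freqs.columns)
    return "".join(pwm.freqs[cols].idxmax(axis=1))


def plot_logo(pwm: PWM, path: str | Path, corrected: bool = False):
    """Render a simple sequence logo (letters scaled by IC contribution).

    A minimal matplotlib rendering: at each position, letters are stacked
    by frequency and the stack height equals the position's information
    content in bits.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ic = pwm.small_sample_corrected_ic() if corrected else pwm.information_content
    fig, ax = plt.subplots(figsize=(max(4, 0.35 * len(pwm.freqs)), 2.5))
    for pos in pwm.freqs.index:
        stack = pwm.freqs.loc[pos]
        stack = stack[stack > 0].sort_values()
        y = 0.0
        for aa, f in stack.items():
            h = f * ic.loc[pos]
            if h <= 0:
                continue
            ax.text(
                pos, y + h / 2, aa, ha="center", va="center",
                fontsize=6 + 14 * min(h / math.log2(20), 1.0), family="monospace",
            )
            y += h
    ax.set_xlim(0.5, len(pwm.freqs) + 0.5)
    ax.set_ylim(0, math.log2(len(pwm.freqs.columns)))
    ax.set_xlabel("position")
    ax.set_ylabel("bits")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


# ---------------------------------------------------------------------------
# Resfiles

_COMMANDS = ("PIKAA", "NATAA", "NOTAA")


class ResfileError(ValueError):
    pass


@dataclass(frozen=True)
class ResfileCommand:
    """A per-position design-constraint command.

    PIKAA: allow only the listed residues; NATAA: keep the native
    identity (repack only); NOTAA: disallow the listed residues.
    """

    res_id: int
    chain: str
    command: str  # PIKAA | NATAA | NOTAA
    residues: str = ""  # argument for PIKAA/NOTAA

    def __post_init__(self) -> None:
        if self.command not in _COMMANDS:
            raise ResfileError(f"unknown resfile command {self.command!r}")
        if self.command in ("PIKAA", "NOTAA") and not self.residues:
            raise ResfileError(f"{self.command} at {self.res_id} needs a residue set")
        if self.command == "NATAA" and self.residues:
            raise ResfileError("NATAA takes no residue argument")

    def render(self) -> str:
        tail = f" {self.residues}" if self.residues else ""
        return f"{self.res_id} {self.chain} {self.command}{tail}"


@dataclass
class ResfileSpec:
    """A resfile: default command(s) before ``start``, then body commands."""

    default_command: str = "PIKAA"
    default_residues: str = CANONICAL_AA
    commands: list[ResfileCommand] = field(default_factory=list)

    def command_at(self, res_id: int, chain: str) -> ResfileCommand | None:
        for cmd in self.commands:
            if cmd.res_id == res_id and cmd.chain == chain:
                return cmd
        return None

    def partition(self) -> dict[str, list[int]]:
        """Positions grouped by command type (for quick inspection)."""
        out: dict[str, list[int]] = {c: [] for c in _COMMANDS}
        for cmd in self.commands:
            out[cmd.command].append(cmd.res_id)
        return {k: sorted(v) for k, v in out.items()}


def parse_resfile(source: str | Path) -> ResfileSpec:
    """Parse resfile text: default command lines, ``start``, body lines."""
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
        text = Path(source).read_text()
    else:
        text = str(source)

    spec = ResfileSpec(default_command="PIKAA", default_residues=CANONICAL_AA)
    seen_start = False
    seen_default = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        if not seen_start:
            if tokens[0].lower() == "start":
                seen_start = True
                continue
            if tokens[0][0].isdigit():
                raise ResfileError(f"line {lineno}: body line before 'start'")
            if tokens[0] not in _COMMANDS:
                raise ResfileError(f"line {lineno}: unknown command {tokens[0]!r}")
            spec.default_command = tokens[0]
            spec.default_residues = tokens[1] if len(tokens) > 1 else ""
            if spec.default_command in ("PIKAA", "NOTAA") and not spec.default_residues:
                raise ResfileError(f"line {lineno}: {tokens[0]} needs a residue set")
            seen_default = True
            continue
        # body: <resnum> <chain> <COMMAND> [args]
        if len(tokens) < 3:
            raise ResfileError(f"line {lineno}: malformed body line {line!r}")
        try:
            res_id = int(tokens[0])
        except ValueError:
            raise ResfileError(f"line {lineno}: residue number expected, got {tokens[0]!r}") from None
        chain, command = tokens[1], tokens[2]
        if command not in _COMMANDS:
            raise ResfileError(f"line {lineno}: unknown command {command!r}")
        residues = tokens[3] if len(tokens) > 3 else ""
        try:
            spec.commands.append(ResfileCommand(res_id, chain, command, residues))
        except ResfileError as exc:
            raise ResfileError(f"line {lineno}: {exc}") from None
    if not seen_start:
        raise ResfileError("no 'start' marker found")
    if not seen_default:
        # a resfile may legally omit the default; keep the PIKAA-all default
        pass
    return spec


def write_resfile(spec: ResfileSpec, path: str | Path | None = None) -> str:
    """Render a resfile; ``parse_resfile(write_resfile(s)) == s``."""
    lines = []
    head = spec.default_command
    if spec.default_residues:
        head += f" {spec.default_residues}"
    lines.append(head)
    lines.append("start")
    lines.extend(cmd.render() for cmd in spec.commands)
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def derive_constraints(
    profile,
    fixed_native: Iterable[int] = (),
    fixed_identity: Mapping[int, str] | None = None,
    disallow_set: str = "ED",
    lipid_threshold: float = 0.25,
    design_positions_exclude: Iterable[int] = (),
    scaffold_sequence: str | None = None,
    chain: str = "E",
) -> ResfileSpec:
    """Derive a design-constraint spec from a fractional-contact profile.

    Rules, in precedence order:

    * ``fixed_native`` positions -> NATAA (identity kept, repack only);
    * ``fixed_identity`` positions -> single-residue PIKAA;
    * positions whose lipid_head + lipid_tail fractional contact is at
      least ``lipid_threshold`` -> NOTAA of ``disallow_set`` (acidic
      residues disfavoured at membrane-facing positions);
    * cysteines of ``scaffold_sequence`` (when given) and
      ``design_positions_exclude`` -> NATAA;
    * everything else falls to the default all-canonical PIKAA.

    A position claimed by two rules with conflicting commands raises.
    """
    if not 0 < lipid_threshold <= 1:
        raise ValueError("lipid_threshold must be in (0, 1]")
    fixed_identity = dict(fixed_identity or {})
    fixed_native = set(fixed_native)
    exclude = set(design_positions_exclude)
    if scaffold_sequence is not None:
        exclude |= {i for i, aa in enumerate(scaffold_sequence, start=1) if aa == "C"}

    conflict = fixed_native & set(fixed_identity)
    if conflict:
        raise ValueError(f"positions both NATAA-fixed and identity-fixed: {sorted(conflict)}")
    conflict = set(fixed_identity) & exclude
    if conflict:
        raise ValueError(
            f"positions both identity-fixed and design-excluded: {sorted(conflict)}"
        )

    values = profile.values
    positions = list(values.index)
    lipid = values.get("lipid_head", 0.0) + values.get("lipid_tail", 0.0)

    commands: list[ResfileCommand] = []
    for pos in positions:
        if pos in fixed_native:
            commands.append(ResfileCommand(pos, chain, "NATAA"))
        elif pos in fixed_identity:
            commands.append(ResfileCommand(pos, chain, "PIKAA", fixed_identity[pos]))
        elif pos in exclude:
            commands.append(ResfileCommand(pos, chain, "NATAA"))
        elif float(lipid.loc[pos]) >= lipid_threshold:
            commands.append(ResfileCommand(pos, chain, "NOTAA", disallow_set))
        # else: default all-canonical PIKAA
    return ResfileSpec(
        default_command="PIKAA", default_residues=CANONICAL_AA, commands=commands
    )
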