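"""Residue-environment contact statistics from multi-model structure frames.

A peptide toxin bound at a channel voltage-sensor sits in a mixed
environment: part protein-protein interface, part lipid bilayer, part
water.  Given simulation frames of the complex written as a multi-model
PDB file, this module classifies every atom into an environment group
(lipid head, lipid tail, water, channel, peptide, ion) and computes, for
each peptide residue, the *fractional contact* with each group: the
fraction of (frame, chain-pair) observations in which any heavy atom of
the residue lies within a distance cutoff (default 3.5 A) of any heavy
atom of the group.  The tetrameric channel binds four peptide copies, so
observations are counted across the interacting chain pairs (e.g. A-E,
B-F, C-G, D-H) as well as across frames.

The contact indicator is binary per (frame, chain-pair, residue, group)
-- "any heavy-atom pair within cutoff" -- not an atom-pair count, and
profile values are exact count ratios.  A per-atom-count weighting is
available via ``ContactParams.weighted`` for comparison.

Polar-interaction detection (hydrogen bonds, salt bridges) uses simple
geometric criteria over donor/acceptor atom-name tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree

__all__ = [
    "StructureFrame",
    "FrameParseError",
    "read_frames",
    "GroupRules",
    "DEFAULT_RULES",
    "classify_atoms",
    "ContactParams",
    "ContactProfile",
    "fractional_contacts",
    "PolarInteraction",
    "PolarCriteria",
    "find_polar_interactions",
    "ENVIRONMENT_GROUPS",
]

#: Environment groups a peptide residue can contact.
ENVIRONMENT_GROUPS = ("lipid_head", "lipid_tail", "water", "channel")

ALL_GROUPS = ENVIRONMENT_GROUPS + ("peptide", "ion", "other")


class FrameParseError(ValueError):
    """Raised for malformed coordinate files (with a line number when known)."""


@dataclass
class StructureFrame:
    """One frame of atomic coordinates as parallel arrays."""

    frame_index: int
    chain: np.ndarray  # str
    res_id: np.ndarray  # int
    res_name: np.ndarray  # str
    atom_name: np.ndarray  # str
    element: np.ndarray  # str, upper-case
    coord: np.ndarray  # (n, 3) float, Angstrom
    is_hydrogen: np.ndarray  # bool; hydrogens are retained but flagged

    def __len__(self) -> int:
        return len(self.res_id)


def _validate_pdb_text(text: str) -> None:
    """Pre-scan ATOM/HETATM records for field errors, reporting line numbers."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise FrameParseError(f"line {lineno}: truncated coordinate record")
        try:
            coords = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            int(line[22:26])
        except ValueError:
            raise FrameParseError(f"line {lineno}: malformed coordinate or residue field") from None
        if not all(math.isfinite(c) for c in coords):
            raise FrameParseError(f"line {lineno}: non-finite coordinate")


def read_frames(source: str | Path) -> list[StructureFrame]:
    """Read a (possibly multi-model) PDB file into structure frames.

    Single-model files yield one frame.  Hydrogens are retained but
    flagged via :attr:`StructureFrame.is_hydrogen`.

    Raises
    ------
    FrameParseError
        On malformed ATOM/HETATM records (with the line number) or when
        the file contains no coordinate records.
    """
    import biotite.structure.io.pdb as pdb

    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
        text = Path(source).read_text()
    else:
        text = str(source)
    _validate_pdb_text(text)
    try:
        pdb_file = pdb.PDBFile.read(StringIO(text))
        stack = pdb_file.get_structure(model=None)
    except Exception as exc:  # biotite raises various error types
        raise FrameParseError(f"cannot parse coordinate file: {exc}") from exc
    if stack.array_length() == 0 or stack.stack_depth() == 0:
        raise FrameParseError("file contains no coordinate records")

    element = np.char.upper(stack.element.astype(str))
    is_h = np.isin(element, ("H", "D"))
    frames = []
    for i in range(stack.stack_depth()):
        frames.append(
            StructureFrame(
                frame_index=i,
                chain=stack.chain_id.astype(str),
                res_id=stack.res_id.astype(int),
                res_name=stack.res_name.astype(str),
                atom_name=stack.atom_name.astype(str),
                element=element,
                coord=np.asarray(stack.coord[i], dtype=float),
                is_hydrogen=is_h,
            )
        )
    return frames


# POPC head/tail partition by atom name.  The head group covers choline,
# phosphate, glycerol and the two ester linkages; the tails are the acyl
# chain carbons C22..C218 (oleoyl, sn-2) and C32..C316 (palmitoyl, sn-3).
# This partition is an explicit, shipped assumption (see docs/methods.md).
_POPC_TAIL_ATOMS = frozenset(
    {f"C2{i}" for i in range(2, 19)} | {f"C3{i}" for i in range(2, 17)}
)

_WATER_RESNAMES = frozenset({"HOH", "TIP3", "TIP", "WAT", "SOL", "SPC", "TIP4"})
_ION_RESNAMES = frozenset({"NA", "CL", "SOD", "CLA", "POT", "K", "MG", "CAL", "ZN"})
# "POP" covers strict readers that truncate the residue name to the
# standard three PDB columns.
_LIPID_RESNAMES = frozenset({"POPC", "POP"})


@dataclass
class GroupRules:
    """Rules assigning every atom to exactly one environment group.

    Assignment precedence: water/ion/lipid residue names first (so a
    crystallographic water placed in a protein chain is still water),
    then peptide/channel chain membership, then ``other``.
    """

    peptide_chains: tuple[str, ...] = ("E", "F", "G", "H")
    channel_chains: tuple[str, ...] = ("A", "B", "C", "D")
    water_resnames: frozenset[str] = _WATER_RESNAMES
    ion_resnames: frozenset[str] = _ION_RESNAMES
    lipid_resnames: frozenset[str] = _LIPID_RESNAMES
    lipid_tail_atoms: frozenset[str] = _POPC_TAIL_ATOMS

    def to_yaml(self, path: str | Path | None = None) -> str:
        payload = {
            "peptide_chains": list(self.peptide_chains),
            "channel_chains": list(self.channel_chains),
            "water_resnames": sorted(self.water_resnames),
            "ion_resnames": sorted(self.ion_resnames),
            "lipid_resnames": sorted(self.lipid_resnames),
            "lipid_tail_atoms": sorted(self.lipid_tail_atoms),
        }
        text = yaml.safe_dump(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "GroupRules":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
            source = Path(source).read_text()
        payload = yaml.safe_load(source)
        return cls(
            peptide_chains=tuple(payload["peptide_chains"]),
            channel_chains=tuple(payload["channel_chains"]),
            water_resnames=frozenset(payload["water_resnames"]),
            ion_resnames=frozenset(payload["ion_resnames"]),
            lipid_resnames=frozenset(payload["lipid_resnames"]),
            lipid_tail_atoms=frozenset(payload["lipid_tail_atoms"]),
        )


DEFAULT_RULES = GroupRules()


def classify_atoms(frame: StructureFrame, rules: GroupRules = DEFAULT_RULES) -> np.ndarray:
    """Assign each atom of ``frame`` to one group; returns an array of labels."""
    present = set(frame.chain)
    missing = [c for c in rules.peptide_chains if c not in present]
    if len(missing) == len(rules.peptide_chains):
        raise ValueError(f"no peptide chain of {rules.peptide_chains} present in frame")

    groups = np.full(len(frame), "other", dtype=object)
    water = np.isin(frame.res_name, list(rules.water_resnames))
    ion = np.isin(frame.res_name, list(rules.ion_resnames))
    lipid = np.isin(frame.res_name, list(rules.lipid_resnames))
    tail = lipid & np.isin(frame.atom_name, list(rules.lipid_tail_atoms))
    head = lipid & ~tail
    peptide = np.isin(frame.chain, list(rules.peptide_chains))
    channel = np.isin(frame.chain, list(rules.channel_chains))

    groups[channel] = "channel"
    groups[peptide] = "peptide"
    groups[head] = "lipid_head"
    groups[tail] = "lipid_tail"
    groups[ion] = "ion"
    groups[water] = "water"
    return groups.astype(str)


@dataclass
class ContactParams:
    """Parameters of the fractional-contact computation."""

    cutoff: float = 3.5  # Angstrom, heavy-atom pair distance
    heavy_atoms_only: bool = True
    chain_pairs: tuple[tuple[str, str], ...] = (("A", "E"), ("B", "F"), ("C", "G"), ("D", "H"))
    weighted: bool = False  # atom-pair-count weighting instead of binary indicator
    brute_force: bool = False  # all-pairs distances instead of a spatial index

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class ContactProfile:
    """Per (peptide residue, group) fractional contact.

    ``counts`` holds integer in-contact observation counts; ``values``
    are the exact ratios counts / n_observations.
    """

    counts: pd.DataFrame  # index: residue position, columns: groups, int
    n_observations: int

    @property
    def values(self) -> pd.DataFrame:
        return self.counts / self.n_observations

    def to_csv(self, path: str | Path | None = None) -> str:
        df = self.values.copy()
        df.insert(0, "n_observations", self.n_observations)
        text = df.to_csv(index_label="position")
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_csv(cls, source: str | Path) -> "ContactProfile":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
            df = pd.read_csv(source, index_col="position")
        else:
            df = pd.read_csv(StringIO(str(source)), index_col="position")
        n_obs = int(df.pop("n_observations").iloc[0])
        counts = (df * n_obs).round().astype(int)
        return cls(counts=counts, n_observations=n_obs)

    @classmethod
    def from_values(cls, values: pd.DataFrame, n_observations: int) -> "ContactProfile":
        counts = (values * n_observations).round().astype(int)
        return cls(counts=counts, n_observations=n_observations)


class _GroupIndex:
    """Distance search against one group's atoms.

    The spatial-index path (cKDTree) and the all-pairs brute force are
    required to agree exactly; tests enforce the contract.
    """

    def __init__(self, coords: np.ndarray, brute_force: bool) -> None:
        self.coords = coords
        self.brute_force = brute_force
        self.tree = cKDTree(coords) if (len(coords) and not brute_force) else None

    def n_within(self, query: np.ndarray, cutoff: float) -> int:
        """Number of (query atom, group atom) pairs within ``cutoff``."""
        if len(self.coords) == 0:
            return 0
        if self.tree is None:
            from scipy.spatial.distance import cdist

            return int((cdist(query, self.coords) <= cutoff).sum())
        return int(sum(len(hits) for hits in self.tree.query_ball_point(query, cutoff)))

    def any_within(self, query: np.ndarray, cutoff: float) -> bool:
        if len(self.coords) == 0:
            return False
        if self.tree is None:
            from scipy.spatial.distance import cdist

            return bool((cdist(query, self.coords) <= cutoff).any())
        d, _ = self.tree.query(query, k=1, distance_upper_bound=cutoff * (1 + 1e-12))
        return bool((d[np.isfinite(d)] <= cutoff).any())


def fractional_contacts(
    frames: Sequence[StructureFrame],
    rules: GroupRules = DEFAULT_RULES,
    params: ContactParams = ContactParams(),
    groups: Sequence[str] = ENVIRONMENT_GROUPS,
) -> ContactProfile:
    """Fractional contact of each peptide residue with each group.

    For every (frame, chain-pair) observation, a residue is in contact
    with a group when any of its heavy atoms lies within
    ``params.cutoff`` of any heavy atom of the group.  The channel group
    is restricted to the paired channel chain; membrane and water atoms
    are shared across pairs but each (frame, pair) still contributes one
    observation, so all groups are normalized by the same denominator
    n_frames x n_pairs.
    """
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    if len(params.chain_pairs) == 0:
        raise ValueError("chain-pair list is empty")

    first = frames[0]
    labels0 = classify_atoms(first, rules)
    pep_chains = {pc for _, pc in params.chain_pairs}
    present = set(first.chain)
    for ch_c, ch_p in params.chain_pairs:
        if ch_p not in present:
            raise ValueError(f"peptide chain {ch_p!r} not present in frames")
        if ch_c not in present:
            raise ValueError(f"channel chain {ch_c!r} not present in frames")

    positions = sorted(set(first.res_id[(np.isin(first.chain, list(pep_chains)))].tolist()))
    if not positions:
        raise ValueError("no peptide residues found for the requested chain pairs")
    counts = pd.DataFrame(0, index=positions, columns=list(groups), dtype=int)

    counts_arr = np.zeros((len(positions), len(groups)), dtype=np.int64)
    pos_index = {p: i for i, p in enumerate(positions)}

    for frame in frames:
        labels = classify_atoms(frame, rules) if frame is not first else labels0
        heavy = ~frame.is_hydrogen if params.heavy_atoms_only else np.ones(len(frame), bool)
        shared_index = {
            g: _GroupIndex(frame.coord[(labels == g) & heavy], params.brute_force)
            for g in groups
            if g != "channel"
        }
        channel_index = {
            ch: _GroupIndex(
                frame.coord[(frame.chain == ch) & (labels == "channel") & heavy],
                params.brute_force,
            )
            for ch in {c for c, _ in params.chain_pairs}
        }
        for ch_channel, ch_peptide in params.chain_pairs:
            pep_mask = (frame.chain == ch_peptide) & heavy
            for pos in positions:
                res_coords = frame.coord[pep_mask & (frame.res_id == pos)]
                if len(res_coords) == 0:
                    raise ValueError(
                        f"residue {pos} of chain {ch_peptide} has no heavy atoms"
                    )
                for gi, g in enumerate(groups):
                    index = channel_index[ch_channel] if g == "channel" else shared_index[g]
                    if params.weighted:
                        counts_arr[pos_index[pos], gi] += index.n_within(
                            res_coords, params.cutoff
                        )
                    elif index.any_within(res_coords, params.cutoff):
                        counts_arr[pos_index[pos], gi] += 1
    counts.loc[positions, list(groups)] = counts_arr

    n_obs = len(frames) * len(params.chain_pairs)
    return ContactProfile(counts=counts, n_observations=n_obs)


# ---------------------------------------------------------------------------
# Polar interactions

_SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "TRP": {"NE1"},
}
_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
}
_CATIONS = {"ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "HIS": {"ND1", "NE2"}}
_ANIONS = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}


@dataclass
class PolarCriteria:
    """Geometric criteria for polar-interaction detection.

    Hydrogen bond: donor-acceptor heavy-atom distance <= 3.5 A; when
    explicit hydrogens are present on the donor, additionally a
    donor-H...acceptor angle >= 120 degrees.  Salt bridge: side-chain
    charged N/O pair <= 4.0 A.
    """

    hbond_distance: float = 3.5
    hbond_angle_min: float = 120.0  # degrees, at the hydrogen
    salt_bridge_distance: float = 4.0


@dataclass(frozen=True)
class AtomRef:
    chain: str
    res_id: int
    res_name: str
    atom_name: str


@dataclass(frozen=True)
class PolarInteraction:
    kind: str  # "hbond" | "salt_bridge"
    donor: AtomRef  # donor or cation
    acceptor: AtomRef  # acceptor or anion
    distance: float


def _atom_refs(frame: StructureFrame, idx: np.ndarray) -> list[AtomRef]:
    return [
        AtomRef(frame.chain[i], int(frame.res_id[i]), frame.res_name[i], frame.atom_name[i])
        for i in idx
    ]


def _hbond_angle_ok(
    frame: StructureFrame, d_idx: int, a_idx: int, min_angle_deg: float
) -> bool:
    """If explicit hydrogens sit on the donor, require D-H...A >= min angle."""
    same_res = (
        (frame.chain == frame.chain[d_idx])
        & (frame.res_id == frame.res_id[d_idx])
        & frame.is_hydrogen
    )
    h_coords = frame.coord[same_res]
    if len(h_coords) == 0:
        return True
    d = frame.coord[d_idx]
    a = frame.coord[a_idx]
    attached = h_coords[np.linalg.norm(h_coords - d, axis=1) <= 1.25]
    if len(attached) == 0:
        return True
    for h in attached:
        v1, v2 = d - h, a - h
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        if math.degrees(math.acos(np.clip(cosang, -1, 1))) >= min_angle_deg:
            return True
    return False


def find_polar_interactions(
    frame: StructureFrame,
    kind: str,
    criteria: PolarCriteria = PolarCriteria(),
    interface_only: bool = False,
    rules: GroupRules = DEFAULT_RULES,
) -> list[PolarInteraction]:
    """All donor/acceptor (or cation/anion) pairs meeting the criterion.

    Results are sorted by distance.  With ``interface_only``, only pairs
    spanning the peptide-channel interface are returned.
    """
    if kind == "hbond":
        donor_table, acceptor_table, cutoff = (
            _SIDECHAIN_DONORS,
            _SIDECHAIN_ACCEPTORS,
            criteria.hbond_distance,
        )
        backbone_donor, backbone_acceptor = {"N"}, {"O", "OXT"}
    elif kind == "salt_bridge":
        donor_table, acceptor_table, cutoff = (
            _CATIONS,
            _ANIONS,
            criteria.salt_bridge_distance,
        )
        backbone_donor, backbone_acceptor = set(), {"OXT"}
    else:
        raise ValueError(f"unknown interaction kind {kind!r}")

    def _select(table: dict[str, set[str]], backbone: set[str]) -> np.ndarray:
        mask = np.zeros(len(frame), dtype=bool)
        for i in range(len(frame)):
            if frame.is_hydrogen[i]:
                continue
            name, res = frame.atom_name[i], frame.res_name[i]
            if name in backbone or name in table.get(res, ()):
                mask[i] = True
        return np.flatnonzero(mask)

    donors = _select(donor_table, backbone_donor)
    acceptors = _select(acceptor_table, backbone_acceptor)
    if len(donors) == 0 or len(acceptors) == 0:
        return []

    out = []
    dist = np.linalg.norm(
        frame.coord[donors][:, None, :] - frame.coord[acceptors][None, :, :], axis=2
    )
    pep = set(rules.peptide_chains)
    cha = set(rules.channel_chains)
    for di, d_idx in enumerate(donors):
        for ai, a_idx in enumerate(acceptors):
            if d_idx == a_idx:
                continue
            if (
                frame.chain[d_idx] == frame.chain[a_idx]
                and frame.res_id[d_idx] == frame.res_id[a_idx]
            ):
                continue  # intra-residue pairs are not interactions
            d = dist[di, ai]
            if d > cutoff:
                continue
            if interface_only:
                chains = {frame.chain[d_idx], frame.chain[a_idx]}
                if not (chains & pep and chains & cha):
                    continue
            if kind == "hbond" and not _hbond_angle_ok(
                frame, d_idx, a_idx, criteria.hbond_angle_min
            ):
                continue
            out.append(
                PolarInteraction(
                    kind=kind,
                    donor=_atom_refs(frame, [d_idx])[0],
                    acceptor=_atom_refs(frame, [a_idx])[0],
                    distance=float(d),
                )
            )
    out.sort(key=lambda p: p.distance)
    return out
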