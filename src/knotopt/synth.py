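"""Synthetic-data generators for every pipeline stage.

The raw inputs of the campaign -- membrane MD trajectories, design-engine
score tables, patch-clamp recordings -- are large and instrument-bound.
These generators emit small, statistically faithful stand-ins with known
planted ground truth, so every downstream computation can be tested
end-to-end: structure frames with planted per-(residue, group) contact
probabilities, scorefiles with known score orderings and an optional
planted sequence motif among the cascade winners, dose-response draws
from known Hill parameters, per-cell AP tables with known dose effects,
and two-component (fast/slow-inactivating) current traces.

Determinism: one top-level seed fans out to per-generator substreams via
``numpy.random.SeedSequence(seed, crc32(label))``, so adding a generator
never perturbs the draws of another, and an identical specification
yields byte-identical output.

Geometry in the frame generator is deliberately minimal -- one
pseudo-atom per group placement; realism is not the goal, classifiability
and the planted contact state are.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ephys import CurrentTrace
from .interface import ENVIRONMENT_GROUPS
from .peptides import CANONICAL_AA
from .pharm import DoseResponse, hill

__all__ = [
    "substream",
    "gen_complex_frames",
    "gen_scorefile",
    "gen_dose_response",
    "gen_ephys_table",
    "TraceComponent",
    "gen_traces",
    "DEFAULT_DOSE_EFFECTS",
]

#: Near/far placement distances (A) around the 3.5 A contact cutoff.
_CONTACT_DIST = 2.5
_NO_CONTACT_DIST = 8.0


def substream(seed: int, label: str) -> np.random.Generator:
    """Independent per-generator random stream derived from one seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(label.encode())]))


# ---------------------------------------------------------------------------
# Structure frames


def _pdb_line(
    serial: int,
    name: str,
    res_name: str,
    chain: str,
    res_id: int,
    xyz: np.ndarray,
    element: str,
    hetero: bool,
) -> str:
    record = "HETATM" if hetero else "ATOM  "
    return (
        f"{record}{serial:>5d} {name:<4s} {res_name:<4s}{chain:1s}{res_id:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}          "
        f"{element:>2s}"
    )


_GROUP_ATOM = {
    # group -> (atom name, residue name, chain, element, hetero, direction)
    "lipid_head": ("P", "POPC", "L", "P", True, np.array([0.0, 0.0, 1.0])),
    "lipid_tail": ("C28", "POPC", "L", "C", True, np.array([0.0, 0.0, -1.0])),
    "water": ("O", "HOH", "W", "O", True, np.array([1.0, 0.0, 0.0])),
    "channel": ("CA", "GLY", None, "C", False, np.array([-1.0, 0.0, 0.0])),
}

_PAIR_SPACING = 1800.0  # A between chain-pair blocks
_RES_SPACING = 50.0  # A between residues along a chain


def _normalize_probs(
    contact_probs, peptide_length: int, groups: Sequence[str]
) -> pd.DataFrame:
    if np.isscalar(contact_probs):
        return pd.DataFrame(
            float(contact_probs), index=range(1, peptide_length + 1), columns=list(groups)
        )
    if isinstance(contact_probs, pd.DataFrame):
        return contact_probs.astype(float)
    # mapping (position, group) -> p, default 0
    df = pd.DataFrame(0.0, index=range(1, peptide_length + 1), columns=list(groups))
    for (pos, group), p in contact_probs.items():
        df.loc[pos, group] = float(p)
    return df


def gen_complex_frames(
    n_frames: int,
    peptide_length: int,
    contact_probs,
    chain_pairs: Sequence[tuple[str, str]] = (("A", "E"), ("B", "F"), ("C", "G"), ("D", "H")),
    seed: int = 0,
    path: str | Path | None = None,
) -> str:
    """Multi-model PDB text with planted per-observation contacts.

    For every (frame, chain-pair, residue, group) an atom of the group is
    placed 2.5 A from the residue's pseudo-atom with the planted
    probability, else 8 A away -- independently per observation, so the
    fractional-contact estimator sees independent Bernoulli draws for
    every group.  Residue and pair blocks are spaced far apart so planted
    states cannot interfere.

    ``contact_probs`` is a scalar, a mapping ``(position, group) -> p``
    or a DataFrame indexed by 1-based position with group columns.
    """
    probs = _normalize_probs(contact_probs, peptide_length, ENVIRONMENT_GROUPS)
    if ((probs < 0) | (probs > 1)).any().any():
        raise ValueError("contact probabilities must be in [0, 1]")
    rng = substream(seed, "complex_frames")

    lines = []
    for fi in range(n_frames):
        lines.append(f"MODEL     {fi + 1:>4d}")
        serial = 1
        group_res_counter = {"L": 0, "W": 0}
        for pi, (chain_channel, chain_peptide) in enumerate(chain_pairs):
            base = np.array([pi * _PAIR_SPACING, 0.0, 0.0])
            channel_res = 0
            for pos in range(1, peptide_length + 1):
                center = base + np.array([0.0, pos * _RES_SPACING, 0.0])
                lines.append(
                    _pdb_line(serial, "CA", "ALA", chain_peptide, pos, center, "C", False)
                )
                serial += 1
                for group in ENVIRONMENT_GROUPS:
                    name, res_name, chain, element, hetero, direction = _GROUP_ATOM[group]
                    contact = rng.random() < probs.loc[pos, group]
                    dist = _CONTACT_DIST if contact else _NO_CONTACT_DIST
                    xyz = center + direction * dist
                    if group == "channel":
                        chain = chain_channel
                        channel_res += 1
                        res_id = channel_res
                    else:
                        group_res_counter[chain] += 1
                        res_id = group_res_counter[chain]
                    lines.append(
                        _pdb_line(serial, name, res_name, chain, res_id, xyz, element, hetero)
                    )
                    serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Scorefiles


def gen_scorefile(
    n_designs: int = 1000,
    score_model: tuple[float, float, float] = (-300.0, 10.0, 0.5),
    ddg_model: tuple[float, float] = (-40.0, 5.0),
    alphabet: str = CANONICAL_AA,
    seq_length: int = 30,
    planted_motif: Mapping[int, str] | None = None,
    motif_enrichment: float = 0.9,
    n_score: int = 100,
    n_ddg: int = 20,
    seed: int = 0,
    path: str | Path | None = None,
) -> str:
    """A ``SCORE:``-dialect scorefile with known score structure.

    Total score and ddG are drawn jointly normal with the given means,
    standard deviations and correlation.  With ``planted_motif`` (1-based
    position -> residue), the designs that the two-stage cascade
    (``n_score`` then ``n_ddg``) would select carry the motif residues
    with probability ``motif_enrichment``, so a consensus over the
    selected set recovers the motif.
    """
    mean_ts, sd_ts, corr = score_model
    mean_dg, sd_dg = ddg_model
    if not -1.0 <= corr <= 1.0:
        raise ValueError("|correlation| must be <= 1")
    rng = substream(seed, "scorefile")

    cov = np.array(
        [[sd_ts**2, corr * sd_ts * sd_dg], [corr * sd_ts * sd_dg, sd_dg**2]]
    )
    scores = rng.multivariate_normal([mean_ts, mean_dg], cov, size=n_designs)
    tags = [f"design_{i:04d}" for i in range(n_designs)]
    seqs = ["".join(rng.choice(list(alphabet), size=seq_length)) for _ in range(n_designs)]

    if planted_motif:
        order1 = sorted(range(n_designs), key=lambda i: (scores[i, 0], tags[i]))[:n_score]
        order2 = sorted(order1, key=lambda i: (scores[i, 1], tags[i]))[:n_ddg]
        for i in order2:
            seq = list(seqs[i])
            for pos, aa in planted_motif.items():
                if rng.random() < motif_enrichment:
                    seq[pos - 1] = aa
            seqs[i] = "".join(seq)

    sasa = rng.normal(1500.0, 100.0, size=n_designs)
    out = StringIO()
    out.write("SCORE: total_score ddg interface_buried_sasa sequence description\n")
    for i in range(n_designs):
        out.write(
            f"SCORE: {scores[i, 0]:10.3f} {scores[i, 1]:9.3f} {sasa[i]:10.1f} "
            f"{seqs[i]} {tags[i]}\n"
        )
    text = out.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Dose-response


def gen_dose_response(
    ic50: float,
    h: float = 1.0,
    concentrations: Sequence[float] = (1.0, 3.0, 10.0, 30.0, 100.0),
    noise_sd: float = 0.05,
    n_cells: int = 3,
    seed: int = 0,
    peptide: str = "synthetic-peptide",
    subtype: str = "hNav1.7",
) -> DoseResponse:
    """Dose-response draws from known Hill parameters.

    Fractions are the Hill curve plus Gaussian noise, truncated to
    [0, 1].  Every cell contributes one point per concentration.
    """
    if ic50 <= 0 or h <= 0:
        raise ValueError("ic50 and h must be positive")
    rng = substream(seed, "dose_response")
    rows = []
    for cell in range(1, n_cells + 1):
        for c in concentrations:
            f = float(hill(c, ic50, h))
            if noise_sd > 0:
                f = float(np.clip(f + rng.normal(0.0, noise_sd), 0.0, 1.0))
            rows.append((float(c), f, f"cell_{cell}"))
    return DoseResponse(
        peptide=peptide,
        subtype=subtype,
        points=pd.DataFrame(rows, columns=["concentration_nM", "fraction_inhibited", "cell_id"]),
    )


# ---------------------------------------------------------------------------
# Per-cell AP tables

#: Dose effects mirroring the magnitude of the oxaliplatin-model data:
#: dose -> (rheobase multiplier, AP survival probability per frequency).
DEFAULT_DOSE_EFFECTS: dict[str, tuple[float, dict[float, float]]] = {
    "0.01": (1.05, {0.1: 1.0, 1.0: 1.0, 3.0: 0.85, 10.0: 0.6}),
    "0.1": (1.15, {0.1: 1.0, 1.0: 0.85, 3.0: 0.65, 10.0: 0.45}),
    "1": (1.5, {0.1: 0.5, 1.0: 0.35, 3.0: 0.25, 10.0: 0.2}),
}


def gen_ephys_table(
    n_cells: int = 10,
    baseline_rheobase_range: tuple[float, float] = (300.0, 3200.0),
    dose_effects: Mapping[str, tuple[float, Mapping[float, float]]] = DEFAULT_DOSE_EFFECTS,
    rheobase_noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """A per-cell AP/rheobase table with known dose effects.

    The stimulus-train protocol is 10 steps at 0.1 Hz and 120 steps at
    1 and 3 Hz; at 10 Hz cells follow only part of the 120-step train
    even at baseline, so the baseline count is drawn uniformly from
    30..120.  Drugged AP counts are binomial draws of the baseline count
    with the planted survival probability; drugged rheobase is baseline
    x multiplier with small lognormal jitter.
    """
    for _, survival in dose_effects.values():
        if any(not 0 <= p <= 1 for p in survival.values()):
            raise ValueError("survival probabilities must be in [0, 1]")
    rng = substream(seed, "ephys_table")
    rows = []
    for i in range(1, n_cells + 1):
        cell = f"Cell {i}"
        rheo0 = float(rng.uniform(*baseline_rheobase_range))
        base_counts = {0.1: 10, 1.0: 120, 3.0: 120, 10.0: int(rng.integers(30, 121))}
        rows.append((cell, "baseline", round(rheo0), *[base_counts[f] for f in (0.1, 1.0, 3.0, 10.0)]))
        for dose, (mult, survival) in dose_effects.items():
            jitter = float(np.exp(rng.normal(0.0, rheobase_noise_sd))) if rheobase_noise_sd else 1.0
            rheo = round(rheo0 * mult * jitter)
            counts = [
                int(rng.binomial(base_counts[f], survival.get(f, 1.0)))
                for f in (0.1, 1.0, 3.0, 10.0)
            ]
            rows.append((cell, dose, rheo, *counts))
    return pd.DataFrame(
        rows,
        columns=["cell_id", "dose", "rheobase_pA", "aps_0.1Hz", "aps_1Hz", "aps_3Hz", "aps_10Hz"],
    )


# ---------------------------------------------------------------------------
# Current traces


@dataclass(frozen=True)
class TraceComponent:
    """One conductance component: a(1 - e^(-t/tau_act)) e^(-t/tau_inact)."""

    amplitude_pA: float  # negative for inward current
    tau_act: float  # s
    tau_inact: float  # s
    fast: bool | None = None  # auto-classified by tau_inact when None

    def __post_init__(self) -> None:
        if self.tau_act <= 0 or self.tau_inact <= 0:
            raise ValueError("time constants must be positive")

    def is_fast(self, threshold: float = 5e-3) -> bool:
        return self.fast if self.fast is not None else self.tau_inact < threshold

    def evaluate(self, t_after_step: np.ndarray) -> np.ndarray:
        t = np.clip(t_after_step, 0.0, None)
        return np.where(
            t_after_step >= 0,
            self.amplitude_pA * (1.0 - np.exp(-t / self.tau_act)) * np.exp(-t / self.tau_inact),
            0.0,
        )

    def window_average(self, t0: float, t1: float) -> float:
        """Closed-form average of the component over [t0, t1] after the step."""
        ti, ta = self.tau_inact, self.tau_act
        k = 1.0 / ti + 1.0 / ta

        def antideriv(t: float) -> float:
            return -ti * np.exp(-t / ti) + np.exp(-k * t) / k

        return self.amplitude_pA * (antideriv(t1) - antideriv(t0)) / (t1 - t0)


def gen_traces(
    components: Sequence[TraceComponent],
    sample_rate: float = 50_000.0,
    step_onset: float = 0.15,
    duration: float = 0.17,
    baseline_offset: float = 0.0,
    noise_sd: float = 0.0,
    capacitance: float | None = 20.0,
    seed: int = 0,
) -> tuple[CurrentTrace, CurrentTrace]:
    """(total, slow-only) current-trace pair around a voltage step.

    The total trace carries all components, the slow-only trace the
    slow-inactivating ones (a drug-resistant current); subtracting them
    recovers the fast component exactly at ``noise_sd=0`` since the same
    noise draw is shared by both traces.
    """
    rng = substream(seed, "traces")
    n = int(round(duration * sample_rate))
    t_after = np.arange(n) / sample_rate - step_onset
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0

    total = np.full(n, baseline_offset, dtype=float) + noise
    slow = np.full(n, baseline_offset, dtype=float) + noise
    for comp in components:
        contribution = comp.evaluate(t_after)
        total += contribution
        if not comp.is_fast():
            slow += contribution
    make = lambda s: CurrentTrace(
        samples=s, sample_rate=sample_rate, step_onset=step_onset, capacitance=capacitance
    )
    return make(total), make(slow)
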