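"""Cleavage-site inference from intact-protein average masses.

An active beta subunit can trim a neighbour's propeptide within the
flexible region III rather than at the canonical Thr1 bond, leaving a
"cross-cut" product intermediate in mass between the full-length and the
fully processed subunit.  Linear-mode MALDI-TOF of such ~25 kDa products
reports average (isotope-abundance-weighted) masses; matching observed
peaks to the theoretical average masses of C-terminal fragments for every
candidate cut position localises the cleavage.  A diagnostic signature of
distributive trimming is a ladder of peaks spaced by roughly two residue
masses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _pt_mass

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Lightest and heaviest average residue masses (Gly, Trp), Da.
MIN_RESIDUE_MASS = 57.05
MAX_RESIDUE_MASS = 186.21
#: Mean residue mass used to convert ladder spacings into residue steps, Da.
MEAN_RESIDUE_MASS = 111.1254

#: Canonical cut position: the fragment starting at mature-chain Thr1.
CANONICAL_CUT = 1


def average_mass(sequence: str) -> float:
    """Average molecular mass (Da) of an unmodified peptide/protein.

    Sum of average residue masses plus one water; no N-terminal
    modifications or Met excision are applied.
    """
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residues in sequence: {sorted(bad)}")
    return float(_pt_mass.calculate_mass(sequence=sequence, average=True))


@dataclass(frozen=True)
class ProteinConstruct:
    """An expression construct: optional tag, propeptide, mature chain.

    ``propeptide`` is the half-open interval ``[start, stop)`` of the
    propeptide within ``sequence`` (0-based construct coordinates); the
    canonical cleavage site is the ``stop`` boundary, so propeptide
    position ``-k`` is construct index ``stop - k`` and mature Thr1 is
    construct index ``stop``.
    """

    id: str
    sequence: str
    propeptide: tuple[int, int]

    def __post_init__(self) -> None:
        start, stop = self.propeptide
        if not (0 <= start < stop <= len(self.sequence)):
            raise ValueError(
                f"propeptide interval {self.propeptide} outside sequence of "
                f"length {len(self.sequence)}"
            )
        bad = set(self.sequence) - STANDARD_AA
        if bad:
            raise ValueError(f"non-standard residues: {sorted(bad)}")

    @property
    def propeptide_length(self) -> int:
        return self.propeptide[1] - self.propeptide[0]

    def index_of(self, position: int) -> int:
        """Construct index of a propeptide position (negative) or of Thr1 (+1)."""
        start, stop = self.propeptide
        if position == CANONICAL_CUT:
            return stop
        if position >= 0:
            raise ValueError("propeptide positions are negative (or +1 for Thr1)")
        idx = stop + position
        if idx < start:
            raise ValueError(
                f"position {position} outside the propeptide (length {self.propeptide_length})"
            )
        return idx

    def fragment_from(self, position: int) -> str:
        """C-terminal fragment produced by cutting N-terminal of ``position``."""
        return self.sequence[self.index_of(position):]


@dataclass
class PeakList:
    """Observed intact-mass peaks, kept sorted by ascending mass."""

    peaks: list[tuple[float, float]]  # (mass Da, intensity)

    def __post_init__(self) -> None:
        if any(m <= 0 for m, _ in self.peaks):
            raise ValueError("peak masses must be positive")
        if any(i < 0 for _, i in self.peaks):
            raise ValueError("intensities must be non-negative")
        self.peaks = sorted(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def masses(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])

    @classmethod
    def from_tsv(cls, path: str) -> "PeakList":
        df = pd.read_csv(path, sep="\t")
        if not {"mass_Da", "intensity"} <= set(df.columns):
            raise ValueError("peak TSV must have columns mass_Da, intensity")
        return cls(peaks=list(zip(df["mass_Da"].astype(float), df["intensity"].astype(float))))

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(self.peaks, columns=["mass_Da", "intensity"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class CleavageHypothesis:
    """A candidate cut N-terminal of ``cut_position`` and its product mass."""

    cut_position: int  # propeptide position of the fragment's first residue; +1 = canonical
    fragment: str
    theoretical_mass: float


def enumerate_cleavage_hypotheses(
    construct: ProteinConstruct,
    window: tuple[int, int] | None = (-26, -1),
) -> list[CleavageHypothesis]:
    """One hypothesis per boundary in ``window`` plus the canonical site.

    ``window`` is a closed interval of propeptide positions (``None`` for
    an empty window); a hypothesis at position ``p`` means the fragment
    begins with residue ``p`` (the scissile bond is N-terminal of ``p``).
    The canonical hypothesis (fragment beginning at Thr1) is always
    appended.  Theoretical masses decrease strictly with later cuts.
    """
    if window is not None:
        lo, hi = window
        if lo > hi:
            raise ValueError(f"window start {lo} > stop {hi}")
        if lo < -construct.propeptide_length or hi > -1:
            raise ValueError(
                f"window {window} outside propeptide (-{construct.propeptide_length}..-1)"
            )
        positions = list(range(lo, hi + 1))
    else:
        positions = []
    positions.append(CANONICAL_CUT)
    return [
        CleavageHypothesis(
            cut_position=p,
            fragment=construct.fragment_from(p),
            theoretical_mass=average_mass(construct.fragment_from(p)),
        )
        for p in positions
    ]


@dataclass(frozen=True)
class PeakAssignment:
    peak_index: int
    observed_mass: float
    cut_position: int
    theoretical_mass: float
    error_da: float  # observed - theoretical


def match_peaks(
    peaks: PeakList,
    hypotheses: Sequence[CleavageHypothesis],
    tolerance: float = 10.0,
) -> list[PeakAssignment]:
    """Greedy unique assignment of peaks to cleavage hypotheses.

    Candidate (peak, hypothesis) pairs within ``tolerance`` Da are ranked
    by absolute mass error; each peak and each hypothesis is used at most
    once.  Peaks with no hypothesis within tolerance stay unassigned.
    The result is deterministic and independent of peak input order.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    masses = peaks.masses
    candidates = []
    for i, m in enumerate(masses):
        for j, hyp in enumerate(hypotheses):
            err = m - hyp.theoretical_mass
            if abs(err) <= tolerance:
                candidates.append((abs(err), i, j, err))
    candidates.sort()
    used_peaks: set[int] = set()
    used_hyps: set[int] = set()
    out: list[PeakAssignment] = []
    for _, i, j, err in candidates:
        if i in used_peaks or j in used_hyps:
            continue
        used_peaks.add(i)
        used_hyps.add(j)
        hyp = hypotheses[j]
        out.append(
            PeakAssignment(
                peak_index=i,
                observed_mass=float(masses[i]),
                cut_position=hyp.cut_position,
                theoretical_mass=hyp.theoretical_mass,
                error_da=float(err),
            )
        )
    out.sort(key=lambda a: a.peak_index)
    return out


def assignments_table(assignments: Iterable[PeakAssignment]) -> pd.DataFrame:
    return pd.DataFrame([a.__dict__ for a in assignments])


@dataclass(frozen=True)
class LadderSeries:
    """A run of peaks with consecutive spacings inside a residue-step window."""

    peak_indices: tuple[int, ...]
    spacings: tuple[float, ...]
    residue_steps: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.peak_indices) < 2:
            raise ValueError("a ladder needs at least two peaks")
        if any(s <= 0 for s in self.spacings):
            raise ValueError("spacings must be positive")

    def __len__(self) -> int:
        return len(self.peak_indices)


def detect_ladder(
    peaks: PeakList,
    min_step: float = 2 * MIN_RESIDUE_MASS,
    max_step: float = 2 * MAX_RESIDUE_MASS,
    min_length: int = 2,
) -> list[LadderSeries]:
    """Find maximal chains of peaks spaced by ``[min_step, max_step]`` Da.

    The default window corresponds to two-residue steps (two glycines up
    to two tryptophans).  A chain is maximal when it cannot be extended at
    either end; chains shorter than ``min_length`` peaks are dropped.
    ``residue_steps`` are each spacing divided by the mean residue mass,
    rounded to the nearest integer.
    """
    if not (0 < min_step < max_step):
        raise ValueError("need max_step > min_step > 0")
    m = peaks.masses
    n = len(m)
    succ: dict[int, list[int]] = {
        i: [j for j in range(i + 1, n) if min_step <= m[j] - m[i] <= max_step]
        for i in range(n)
    }
    has_pred = {j for outs in succ.values() for j in outs}
    series: list[LadderSeries] = []

    def extend(chain: list[int]) -> None:
        nexts = succ[chain[-1]]
        if not nexts:
            if len(chain) >= min_length:
                spac = tuple(float(m[b] - m[a]) for a, b in zip(chain, chain[1:]))
                steps = tuple(int(round(s / MEAN_RESIDUE_MASS)) for s in spac)
                series.append(
                    LadderSeries(peak_indices=tuple(chain), spacings=spac, residue_steps=steps)
                )
            return
        for j in nexts:
            extend(chain + [j])

    for i in range(n):
        if i not in has_pred:
            extend([i])
    return series
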