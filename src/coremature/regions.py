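"""Propeptide region segmentation and composition statistics.

Bacterial proteasome beta subunits carry an N-terminal propeptide that is
removed during core-particle (CP) maturation.  Propeptide residues are
numbered with negative integers: residue -1 sits immediately N-terminal of
the cleavage site and the catalytic threonine of the mature chain is +1.
The propeptide divides into three regions with distinct conservation
behaviour:

* region I   -- N-terminal, poorly conserved (default -65..-43),
* region II  -- the structured "central box" that contacts the alpha ring
  (default -42..-27),
* region III -- a glycine-rich flexible linker running into the cleavage
  site (default -26..-1).

This module maps alignment columns onto that coordinate system, slices an
alignment into the three regions, and computes per-region amino-acid
composition together with a hypergeometric enrichment test (the statistic
used to show that the glycine content of region III is far above chance).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

#: Region boundaries (closed intervals of propeptide positions) for the
#: R. erythropolis Prcbeta1 reference numbering.
DEFAULT_BOUNDARIES: dict[str, tuple[int, int]] = {
    "I": (-65, -43),
    "II": (-42, -27),
    "III": (-26, -1),
}


class RegionSchemeError(ValueError):
    """Raised when a region scheme violates its structural invariants."""


@dataclass(frozen=True)
class RegionScheme:
    """Partition of the propeptide coordinate range into ordered regions.

    Parameters
    ----------
    boundaries
        Map from region id to a closed ``(start, stop)`` interval of
        propeptide positions (negative integers, ``start <= stop``).
        Intervals must be disjoint, contiguous and ordered I < II < III.
    cleavage_site
        The boundary convention: position 0 marks the scissile bond, so
        every propeptide position is strictly negative.
    """

    boundaries: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDARIES)
    )
    cleavage_site: int = 0

    def __post_init__(self) -> None:
        items = list(self.boundaries.items())
        if not items:
            raise RegionSchemeError("region scheme has no regions")
        prev_stop = None
        for region, (start, stop) in items:
            if start > stop:
                raise RegionSchemeError(f"region {region}: start {start} > stop {stop}")
            if stop >= self.cleavage_site:
                raise RegionSchemeError(
                    f"region {region}: positions must be < {self.cleavage_site}"
                )
            if prev_stop is not None and start != prev_stop + 1:
                raise RegionSchemeError(
                    f"region {region} does not abut the previous region "
                    f"(starts at {start}, expected {prev_stop + 1})"
                )
            prev_stop = stop

    @property
    def region_ids(self) -> list[str]:
        return list(self.boundaries)

    @property
    def span(self) -> tuple[int, int]:
        """First and last propeptide position covered by the scheme."""
        starts = [b[0] for b in self.boundaries.values()]
        stops = [b[1] for b in self.boundaries.values()]
        return min(starts), max(stops)

    @property
    def propeptide_length(self) -> int:
        lo, hi = self.span
        return hi - lo + 1

    def region_of(self, position: int) -> str:
        """Region id containing a propeptide position."""
        for region, (start, stop) in self.boundaries.items():
            if start <= position <= stop:
                return region
        raise KeyError(f"position {position} outside scheme span {self.span}")

    def region_positions(self, region: str) -> range:
        start, stop = self.boundaries[region]
        return range(start, stop + 1)

    @classmethod
    def from_json(cls, path: str) -> "RegionScheme":
        with open(path) as fh:
            raw = json.load(fh)
        boundaries = {k: tuple(v) for k, v in raw["boundaries"].items()}
        return cls(boundaries=boundaries, cleavage_site=raw.get("cleavage_site", 0))


DEFAULT_SCHEME = RegionScheme()


@dataclass
class AlignedPropeptideSet:
    """A propeptide alignment with reference-anchored column coordinates.

    ``column_map`` assigns a propeptide position to every alignment column
    in which the reference row has a residue; reference-gap columns carry
    no position and are excluded from all region statistics.
    """

    rows: dict[str, str]
    reference_id: str
    column_map: dict[int, int]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"alignment rows differ in length: {sorted(lengths)}")
        if self.reference_id not in self.rows:
            raise KeyError(f"reference {self.reference_id!r} not in alignment")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def reference_row(self) -> str:
        return self.rows[self.reference_id]

    def columns_for_positions(self, positions) -> list[int]:
        wanted = set(positions)
        return sorted(c for c, p in self.column_map.items() if p in wanted)


def read_alignment_fasta(path: str) -> dict[str, str]:
    """Read an aligned FASTA file into an ordered id -> row mapping."""
    from Bio import SeqIO

    rows = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
    if not rows:
        raise ValueError(f"no sequences found in {path}")
    return rows


def write_alignment_fasta(aln: AlignedPropeptideSet, path: str) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=i, description="") for i, s in aln.rows.items()]
    seqio_write(records, path, "fasta")


def map_reference_coordinates(
    rows: Mapping[str, str],
    reference_id: str,
    scheme: RegionScheme = DEFAULT_SCHEME,
) -> AlignedPropeptideSet:
    """Anchor alignment columns to reference propeptide positions.

    The ungapped reference is required to have exactly the propeptide
    length implied by ``scheme`` (65 for the default).  Successive non-gap
    reference columns receive positions ``-L .. -1``; columns where the
    reference has a gap map to no position.
    """
    if reference_id not in rows:
        raise KeyError(f"reference {reference_id!r} not present in alignment")
    ref = rows[reference_id]
    ungapped = [i for i, ch in enumerate(ref) if ch != GAP]
    L = len(ungapped)
    expected = scheme.propeptide_length
    if L != expected:
        raise ValueError(
            f"reference has {L} residues but the scheme requires {expected}"
        )
    bad = [ref[i] for i in ungapped if ref[i] not in AMINO_ACIDS]
    if bad:
        raise ValueError(f"reference contains ambiguity characters: {sorted(set(bad))}")
    column_map = {col: pos for col, pos in zip(ungapped, range(-L, 0))}
    return AlignedPropeptideSet(rows=dict(rows), reference_id=reference_id, column_map=column_map)


def segment_regions(
    aln: AlignedPropeptideSet,
    scheme: RegionScheme = DEFAULT_SCHEME,
) -> dict[str, dict[str, str]]:
    """Slice every row into per-region (possibly gapped) alignment slices.

    Region membership is decided purely by reference coordinates: a column
    belongs to the region containing its mapped position.  Returns
    ``{sequence_id: {region_id: slice}}``; concatenating a row's slices
    reconstructs its propeptide columns exactly once.
    """
    lo, hi = scheme.span
    mapped = set(aln.column_map.values())
    missing = [p for p in range(lo, hi + 1) if p not in mapped]
    if missing:
        raise ValueError(f"scheme positions not mapped to any column: {missing}")
    region_cols = {
        region: aln.columns_for_positions(scheme.region_positions(region))
        for region in scheme.region_ids
    }
    out: dict[str, dict[str, str]] = {}
    for seq_id, row in aln.rows.items():
        out[seq_id] = {
            region: "".join(row[c] for c in cols) for region, cols in region_cols.items()
        }
    return out


@dataclass
class CompositionTable:
    """Per-region amino-acid counts and frequencies."""

    counts: pd.DataFrame  # index: region ids, columns: 20 amino acids
    totals: pd.Series

    @property
    def frequencies(self) -> pd.DataFrame:
        tot = self.totals.replace(0, np.nan)
        return self.counts.div(tot, axis=0).fillna(0.0)

    def frequency(self, region: str, residue: str) -> float:
        return float(self.frequencies.loc[region, residue])

    def to_tsv(self, path: str) -> None:
        self.counts.assign(total=self.totals).to_csv(path, sep="\t")


def composition(
    slices: Mapping[str, Mapping[str, str]],
    on_unknown: str = "error",
) -> CompositionTable:
    """Count residues per region over all sequences, ignoring gaps.

    ``on_unknown`` controls non-standard residue characters: ``"error"``
    (default) raises, ``"skip"`` drops them from the counts.
    """
    if not slices:
        raise ValueError("no sequences to tabulate")
    if on_unknown not in ("error", "skip"):
        raise ValueError(f"on_unknown must be 'error' or 'skip', got {on_unknown!r}")
    regions = list(next(iter(slices.values())))
    counts = {r: dict.fromkeys(AMINO_ACIDS, 0) for r in regions}
    for seq_id, per_region in slices.items():
        for region, chunk in per_region.items():
            for ch in chunk:
                if ch == GAP:
                    continue
                if ch not in AMINO_ACIDS:
                    if on_unknown == "error":
                        raise ValueError(
                            f"unknown residue {ch!r} in sequence {seq_id!r}, region {region}"
                        )
                    continue
                counts[region][ch] += 1
    frame = pd.DataFrame(counts).T.reindex(columns=list(AMINO_ACIDS)).fillna(0).astype(int)
    return CompositionTable(counts=frame, totals=frame.sum(axis=1))


@dataclass
class EnrichmentResult:
    """Upper-tail hypergeometric enrichment of one residue in one region."""

    region: str
    residue: str
    observed_count: int  # k: residue occurrences in the region
    sample_size: int  # n: residues in the region
    background_successes: int  # K: residue occurrences in the population
    population: int  # N: all residues across regions
    p_value: float
    fold_enrichment: float

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "residue": self.residue,
            "k": self.observed_count,
            "n": self.sample_size,
            "K": self.background_successes,
            "N": self.population,
            "p_value": self.p_value,
            "fold_enrichment": self.fold_enrichment,
        }


def glycine_enrichment(
    table: CompositionTable,
    region: str,
    residue: str = "G",
) -> EnrichmentResult:
    """Hypergeometric upper-tail test for residue enrichment in a region.

    The population is all residues of all regions in the table (the full
    propeptide set of the alignment); drawing ``n`` residues (the region)
    without replacement, the p-value is ``P(X >= k)`` for
    ``X ~ Hypergeom(N, K, n)``.
    """
    if region not in table.counts.index:
        raise KeyError(f"region {region!r} not in composition table")
    N = int(table.totals.sum())
    K = int(table.counts[residue].sum())
    n = int(table.totals.loc[region])
    k = int(table.counts.loc[region, residue])
    if n == 0:
        raise ValueError(f"region {region!r} contains no residues")
    p = float(stats.hypergeom(N, K, n).sf(k - 1))
    fold = (k / n) / (K / N) if K > 0 else math.inf
    return EnrichmentResult(
        region=region,
        residue=residue,
        observed_count=k,
        sample_size=n,
        background_successes=K,
        population=N,
        p_value=p,
        fold_enrichment=fold,
    )


def binomial_enrichment(
    table: CompositionTable,
    region: str,
    background_frequency: float,
    residue: str = "G",
) -> EnrichmentResult:
    """One-sided binomial variant against a fixed background frequency.

    Useful when the null is an external composition (e.g. the ~8% glycine
    average of globular proteins) rather than the alignment itself.
    """
    if not 0.0 < background_frequency < 1.0:
        raise ValueError("background_frequency must be in (0, 1)")
    n = int(table.totals.loc[region])
    k = int(table.counts.loc[region, residue])
    if n == 0:
        raise ValueError(f"region {region!r} contains no residues")
    p = float(stats.binomtest(k, n, background_frequency, alternative="greater").pvalue)
    fold = (k / n) / background_frequency
    return EnrichmentResult(
        region=region,
        residue=residue,
        observed_count=k,
        sample_size=n,
        background_successes=-1,
        population=-1,
        p_value=p,
        fold_enrichment=fold,
    )


def region_length_stats(slices: Mapping[str, Mapping[str, str]]) -> pd.DataFrame:
    """Mean/sd/min/max of ungapped per-sequence region lengths."""
    if not slices:
        raise ValueError("no sequences")
    records = []
    for seq_id, per_region in slices.items():
        for region, chunk in per_region.items():
            records.append(
                {"sequence": seq_id, "region": region, "length": sum(ch != GAP for ch in chunk)}
            )
    df = pd.DataFrame(records)
    out = df.groupby("region", sort=False)["length"].agg(["mean", "std", "min", "max"])
    return out.rename(columns={"std": "sd"}).fillna({"sd": 0.0})
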