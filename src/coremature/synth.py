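"""Synthetic inputs for every stage of the maturation pipeline.

Real inputs to these analyses are a curated multiple sequence alignment
of bacterial beta-subunit N termini, a CP crystal structure, and
MALDI-TOF peak lists of reconstituted samples.  None of these are
required for testing the machinery: this module generates
region-structured alignments with tunable per-region composition, an
idealized two-ring 14-site active-site geometry, mass ladders from
planted cleavage positions with noise and decoys, and half-proteasome
pools with binomial subunit-composition mixtures.  Every generator is a
pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .geometry import ActiveSiteSet, AnchorSet, Site, N_PER_RING
from .masses import PeakList, ProteinConstruct, average_mass
from .regions import (
    AMINO_ACIDS,
    GAP,
    AlignedPropeptideSet,
    DEFAULT_SCHEME,
    RegionScheme,
    map_reference_coordinates,
)
from .simulate import HPState, SubunitSpec, SubunitState

# Synthetic 65-residue reference propeptide laid out like the R.e. Prcbeta1
# coordinate system: region I (-65..-43) weakly constrained, region II
# (-42..-27) the structured central box, region III (-26..-1) a Gly-rich
# flexible linker with an Arg at -24 (the last structured residue used as
# the spanning anchor).  The sequence itself is invented.
DEFAULT_REFERENCE_ID = "ref|synthetic_Re_like"
DEFAULT_REFERENCE_PROPEPTIDE = (
    "MTDLNHEGFFAAPVQSALRETGT"  # region I, 23 aa (~9% Gly)
    + "ELVVSITFKDNVVLAS"  # region II, 16 aa (no Gly)
    + "AGRSELGAGMSAADSNGQMVGAHTVS"  # region III, 26 aa, ~19% Gly, Arg at -24
)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def _uniform_composition() -> np.ndarray:
    return np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))


def glycine_biased_composition(glycine_frequency: float) -> np.ndarray:
    """20-vector with the given Gly frequency, remainder spread uniformly."""
    if not 0 <= glycine_frequency <= 1:
        raise ValueError("glycine_frequency must be in [0, 1]")
    vec = np.full(len(AMINO_ACIDS), (1.0 - glycine_frequency) / (len(AMINO_ACIDS) - 1))
    vec[_AA_INDEX["G"]] = glycine_frequency
    return vec


def _coerce_composition(comp) -> np.ndarray:
    if isinstance(comp, Mapping):
        vec = np.zeros(len(AMINO_ACIDS))
        for aa, f in comp.items():
            if aa not in _AA_INDEX:
                raise ValueError(f"unknown amino acid {aa!r} in composition")
            vec[_AA_INDEX[aa]] = f
    else:
        vec = np.asarray(comp, dtype=float)
    if vec.shape != (len(AMINO_ACIDS),):
        raise ValueError("composition must have 20 entries")
    if (vec < 0).any() or abs(vec.sum() - 1.0) > 1e-9:
        raise ValueError("composition frequencies must be >= 0 and sum to 1 (1e-9)")
    return vec


@dataclass
class SyntheticAlignmentSpec:
    """Recipe for a region-structured propeptide alignment.

    ``per_region_composition`` maps region id to a 20-entry amino-acid
    frequency vector (or ``{aa: freq}`` mapping); ``conservation`` is the
    fraction of columns copied verbatim from the reference in every row;
    ``gap_rate`` introduces gaps into non-reference rows.
    """

    n_sequences: int = 256
    region_scheme: RegionScheme = field(default_factory=lambda: DEFAULT_SCHEME)
    per_region_composition: dict = field(
        default_factory=lambda: {
            "I": glycine_biased_composition(0.082),
            "II": glycine_biased_composition(0.0024),
            "III": glycine_biased_composition(0.184),
        }
    )
    conservation: float = 0.3
    gap_rate: float = 0.0
    seed: int = 0
    reference: str = DEFAULT_REFERENCE_PROPEPTIDE
    reference_id: str = DEFAULT_REFERENCE_ID

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        if not 0 <= self.conservation <= 1:
            raise ValueError("conservation must be in [0, 1]")
        if not 0 <= self.gap_rate < 1:
            raise ValueError("gap_rate must be in [0, 1)")
        self.per_region_composition = {
            r: _coerce_composition(c) for r, c in self.per_region_composition.items()
        }
        missing = set(self.region_scheme.region_ids) - set(self.per_region_composition)
        if missing:
            raise ValueError(f"no composition for regions {sorted(missing)}")
        if len(self.reference) != self.region_scheme.propeptide_length:
            raise ValueError(
                f"reference length {len(self.reference)} does not match scheme "
                f"({self.region_scheme.propeptide_length})"
            )


def gen_alignment(spec: SyntheticAlignmentSpec) -> AlignedPropeptideSet:
    """Generate a gapless-reference alignment per the spec; deterministic in seed.

    Conserved columns (a Bernoulli(``conservation``) draw per column,
    shared by all rows) copy the reference residue; other columns draw
    i.i.d. from the column's region composition.  Gaps, when enabled, are
    placed only in non-reference rows.
    """
    rng = np.random.default_rng(spec.seed)
    scheme = spec.region_scheme
    L = scheme.propeptide_length
    lo, _ = scheme.span
    aas = np.array(list(AMINO_ACIDS))
    conserved = rng.random(L) < spec.conservation
    rows: dict[str, str] = {spec.reference_id: spec.reference}
    n_synth = spec.n_sequences - 1
    if n_synth > 0:
        chars = np.empty((n_synth, L), dtype="<U1")
        for region in scheme.region_ids:
            cols = [p - lo for p in scheme.region_positions(region)]
            comp = spec.per_region_composition[region]
            draws = rng.choice(len(aas), size=(n_synth, len(cols)), p=comp)
            chars[:, cols] = aas[draws]
        chars[:, conserved] = np.array(list(spec.reference))[conserved]
        if spec.gap_rate > 0:
            gap_mask = rng.random(chars.shape) < spec.gap_rate
            chars[gap_mask] = GAP
        for s in range(n_synth):
            rows[f"synt|{s:04d}"] = "".join(chars[s])
    return map_reference_coordinates(rows, spec.reference_id, scheme)


@dataclass
class SyntheticGeometrySpec:
    """Idealized two-ring active-site geometry (synthetic stand-in for a
    crystal structure).

    Seven sites per ring at angles ``2*pi*i/7`` on a circle of
    ``ring_radius``; ring B is rotated by ``twist`` degrees and offset
    axially by ``ring_separation``.  Anchors sit at a fixed
    radial/axial offset from their site.  Defaults approximate the scale
    of the R.e. CP interior (adjacent catalytic threonines > 24 A apart).
    """

    ring_radius: float = 28.0
    ring_separation: float = 30.0
    twist: float = 360.0 / 14.0
    anchor_radial_offset: float = 6.0
    anchor_axial_offset: float = 4.0
    seed: int = 0
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.ring_radius <= 0:
            raise ValueError("ring_radius must be > 0")
        if self.ring_separation < 0:
            raise ValueError("ring_separation must be >= 0")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


def gen_ring_geometry(spec: SyntheticGeometrySpec) -> tuple[ActiveSiteSet, AnchorSet]:
    """Place 14 sites and their anchors on the idealized two-ring geometry."""
    rng = np.random.default_rng(spec.seed)
    sites: list[Site] = []
    anchors = AnchorSet()
    for ring, z, twist in (("A", 0.0, 0.0), ("B", spec.ring_separation, spec.twist)):
        # anchors offset outward radially and axially toward the other ring
        axial_sign = 1.0 if ring == "A" else -1.0
        for i in range(N_PER_RING):
            theta = 2 * np.pi * i / N_PER_RING + np.deg2rad(twist)
            base = np.array(
                [spec.ring_radius * np.cos(theta), spec.ring_radius * np.sin(theta), z]
            )
            if spec.jitter_sd > 0:
                base = base + rng.normal(0.0, spec.jitter_sd, size=3)
            site = Site(ring=ring, index=i, xyz=tuple(map(float, base)))
            sites.append(site)
            r_anchor = spec.ring_radius + spec.anchor_radial_offset
            anchor = np.array(
                [
                    r_anchor * np.cos(theta),
                    r_anchor * np.sin(theta),
                    z + axial_sign * spec.anchor_axial_offset,
                ]
            )
            anchors.anchors[site.site_id] = tuple(map(float, anchor))
    return ActiveSiteSet(sites=sites), anchors


def write_geometry_pdb(
    site_set: ActiveSiteSet, anchors: AnchorSet, path: str
) -> None:
    """Write one CA pseudo-atom per site (THR) and per anchor (ARG).

    Sites go to chains A/B (residues 1..7); anchors to chains C/D with the
    residue number of their site, so the file round-trips through
    :func:`coremature.geometry.load_structure` with default selectors.
    """
    import gemmi

    st = gemmi.Structure()
    st.name = "synthetic-cp-sites"
    model = gemmi.Model("1")
    site_chain = {"A": gemmi.Chain("A"), "B": gemmi.Chain("B")}
    anchor_chain = {"A": gemmi.Chain("C"), "B": gemmi.Chain("D")}

    def add_residue(chain, name, seqid, xyz):
        res = gemmi.Residue()
        res.name = name
        res.seqid = gemmi.SeqId(seqid, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*xyz)
        atom.occ = 1.0
        res.add_atom(atom)
        chain.add_residue(res)

    for site in sorted(site_set.sites, key=lambda s: (s.ring, s.index)):
        add_residue(site_chain[site.ring], "THR", site.index + 1, site.xyz)
        if site.site_id in anchors:
            add_residue(
                anchor_chain[site.ring], "ARG", site.index + 1, anchors.anchors[site.site_id]
            )
    for ch in (*site_chain.values(), *anchor_chain.values()):
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


@dataclass
class SyntheticPeakSpec:
    """Planted-cleavage peak list recipe.

    One peak per cut position at the theoretical average mass of the
    C-terminal fragment, Gaussian-perturbed with ``mass_noise_sd``;
    ``n_decoys`` uniform random peaks are added over
    [min true mass - 2 kDa, max true mass + 2 kDa].
    """

    construct: ProteinConstruct
    cut_positions: Sequence[int] = (-9, -7, -5, -3)
    mass_noise_sd: float = 0.0
    n_decoys: int = 0
    seed: int = 0
    decoy_margin: float = 2000.0

    def __post_init__(self) -> None:
        if self.mass_noise_sd < 0:
            raise ValueError("mass_noise_sd must be >= 0")
        if self.n_decoys < 0:
            raise ValueError("n_decoys must be >= 0")
        if not self.cut_positions:
            raise ValueError("at least one cut position is required")
        for p in self.cut_positions:
            if not (-self.construct.propeptide_length <= p <= -1):
                raise ValueError(
                    f"cut position {p} outside the propeptide "
                    f"(-{self.construct.propeptide_length}..-1)"
                )


def gen_peaklist(spec: SyntheticPeakSpec) -> PeakList:
    """Peak list with planted cut masses, noise and decoys; deterministic in seed."""
    rng = np.random.default_rng(spec.seed)
    true_masses = [
        average_mass(spec.construct.fragment_from(p)) for p in spec.cut_positions
    ]
    peaks = []
    for m in true_masses:
        obs = m + (rng.normal(0.0, spec.mass_noise_sd) if spec.mass_noise_sd > 0 else 0.0)
        peaks.append((float(obs), 1.0))
    if spec.n_decoys:
        lo = min(true_masses) - spec.decoy_margin
        hi = max(true_masses) + spec.decoy_margin
        lo = max(lo, 1.0)
        for m in rng.uniform(lo, hi, size=spec.n_decoys):
            peaks.append((float(m), 0.2))
    return PeakList(peaks=peaks)


def make_demo_construct(
    id: str = "beta_demo",
    tag: str = "MGSSHHHHHHSSGLVPRGSH",
    mature_length: int = 40,
    reference: str = DEFAULT_REFERENCE_PROPEPTIDE,
) -> ProteinConstruct:
    """A synthetic tagged beta-subunit construct around the reference propeptide."""
    mature = ("TTIVGLVFRDGVMLAADTRSSMGGLIASDSVKKVHYLAPN" * 2)[:mature_length]
    seq = tag + reference + mature
    start = len(tag)
    return ProteinConstruct(id=id, sequence=seq, propeptide=(start, start + len(reference)))


def gen_mixture_hp_pool(
    ratio: float,
    n_hp: int,
    species_a: SubunitSpec,
    species_b: SubunitSpec,
    seed: int = 0,
) -> list[HPState]:
    """HP pool in which each ring draws its species-a count ~ Binomial(7, ratio).

    Emulates reconstitution of two beta variants at a molar ratio: with
    equal incorporation efficiency the per-HP composition is binomial
    around the input ratio.  Subunit positions are shuffled per HP.
    """
    if not 0 <= ratio <= 1:
        raise ValueError("ratio must be in [0, 1]")
    if n_hp < 1:
        raise ValueError("n_hp must be >= 1")
    rng = np.random.default_rng(seed)
    pool = []
    for _ in range(n_hp):
        n_a = int(rng.binomial(N_PER_RING, ratio))
        specs = [species_a] * n_a + [species_b] * (N_PER_RING - n_a)
        order = rng.permutation(N_PER_RING)
        pool.append(HPState(subunits=[SubunitState(spec=specs[i]) for i in order]))
    return pool
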