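"""Coordinate system, landmark map, and structural-variant liftover.

The model locus is a single 3.3-Mb captured region (chr13:54,000,001-57,300,000
at 5-kb bins) carrying a developmental gene promoter (``P``), its enhancers
(``PelB``, ``PDE``, ``RA4``, ``Pen``), a polycomb-repressed neighbour gene
(``N``) and a set of oriented CTCF sites. Structural-variant alleles are
described as ordered edit operations (inversion, deletion, insertion) on the
reference sequence; the resulting allele-to-reference coordinate map is the
piecewise-affine map induced by the edited segment order.

Coordinates are 1-based and inclusive throughout, so the printed region length
is ``end - start + 1``. Bin ``k`` covers ``[start + k*B, start + (k+1)*B - 1]``
for bin size ``B``. All structural-variant breakpoints must fall on bin
boundaries; the analyses operate at bin resolution and sub-bin breakpoints are
rejected rather than silently split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, MappingError

__all__ = [
    "GenomicInterval",
    "CTCFSite",
    "LandmarkMap",
    "SVOperation",
    "AlleleSpec",
    "build_reference_locus",
    "allele_presets",
    "liftover_point",
    "position_in_allele",
    "interval_in_allele",
    "allele_bin_map",
    "remap_matrix",
    "interval_to_bed",
    "interval_from_bed",
    "DEFAULT_REGION",
    "DEFAULT_BIN_SIZE",
]

DEFAULT_BIN_SIZE = 5_000
DEFAULT_REGION = ("chr13", 54_000_001, 57_300_000)


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, inclusive interval on one chromosome.

    ``assembly_tag`` distinguishes reference coordinates ("reference") from a
    rearranged allele's own coordinate system (the allele name).
    """

    chrom: str
    start: int
    end: int
    assembly_tag: str = "reference"

    def __post_init__(self):
        if self.start < 1:
            raise ConfigurationError(f"interval start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ConfigurationError(
                f"interval start {self.start} exceeds end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start <= other.end and other.start <= self.end)


def interval_to_bed(iv: GenomicInterval) -> tuple[str, int, int]:
    """Convert to BED convention (0-based, half-open)."""
    return (iv.chrom, iv.start - 1, iv.end)


def interval_from_bed(chrom: str, start0: int, end0: int,
                      assembly_tag: str = "reference") -> GenomicInterval:
    """Build an interval from BED fields (0-based, half-open)."""
    return GenomicInterval(chrom, start0 + 1, end0, assembly_tag)


@dataclass(frozen=True)
class CTCFSite:
    """An oriented CTCF site. Orientation is '+' (forward) or '-' (reverse)."""

    pos: int
    orientation: str

    def __post_init__(self):
        if self.orientation not in ("+", "-"):
            raise ConfigurationError(
                f"CTCF orientation must be '+' or '-', got {self.orientation!r}")


# Landmark offsets from the promoter, in bp. Pen sits 400 kb from the
# promoter; RA4 and PDE at 225 kb and 116 kb; PelB is promoter-proximal and
# the repressed neighbour gene N lies on the opposite side of the promoter.
_DEFAULT_OFFSETS = {
    "P": 0,
    "PelB": 30_000,
    "PDE": 116_000,
    "RA4": 225_000,
    "Pen": 400_000,
    "N": -600_000,
}
_PROMOTER_OFFSET_FROM_REGION_START = 1_500_000
# Length of the mobilised enhancer fragment (bin-aligned).
_PEN_FRAGMENT_LEN = 10_000
# Oriented CTCF sites as offsets from the promoter.
_DEFAULT_CTCF_OFFSETS = [
    (-800_000, "-"),
    (-150_000, "+"),
    (50_000, "+"),
    (150_000, "-"),
    (250_000, "+"),
    (350_000, "-"),
    (500_000, "-"),
    (1_000_000, "+"),
]


@dataclass
class LandmarkMap:
    """Named landmark positions and CTCF sites on the reference locus."""

    region: GenomicInterval
    bin_size: int
    landmarks: dict[str, int]
    ctcf_sites: list[CTCFSite]
    pen_fragment: GenomicInterval = None  # interval mobilised by SV presets

    @property
    def n_bins(self) -> int:
        return self.region.length // self.bin_size

    def bin_of(self, pos: int) -> int:
        if not self.region.contains(pos):
            raise ConfigurationError(
                f"position {pos} outside region "
                f"{self.region.chrom}:{self.region.start}-{self.region.end}")
        return (pos - self.region.start) // self.bin_size

    def distance(self, a: str, b: str) -> int:
        return abs(self.landmarks[a] - self.landmarks[b])


def build_reference_locus(config: dict | None = None) -> LandmarkMap:
    """Build the deterministic landmark map of the synthetic locus.

    ``config`` may override ``region`` (chrom, start, end), ``bin_size``,
    ``promoter_offset``, ``landmark_offsets`` and ``ctcf_offsets`` (both
    relative to the promoter). Defaults reproduce the printed spacings:
    Pen-P = 400 kb, RA4-P = 225 kb, PDE-P = 116 kb.
    """
    config = dict(config or {})
    chrom, start, end = config.get("region", DEFAULT_REGION)
    bin_size = config.get("bin_size", DEFAULT_BIN_SIZE)
    region = GenomicInterval(chrom, start, end)
    if region.length % bin_size != 0:
        raise ConfigurationError(
            f"bin size {bin_size} does not divide region length {region.length}")
    p_offset = config.get("promoter_offset", _PROMOTER_OFFSET_FROM_REGION_START)
    offsets = dict(_DEFAULT_OFFSETS, **config.get("landmark_offsets", {}))
    promoter = region.start + p_offset
    landmarks = {name: promoter + off for name, off in offsets.items()}
    for name, pos in landmarks.items():
        if not region.contains(pos):
            raise ConfigurationError(
                f"landmark {name} at {pos} falls outside the region")
    ctcf_offsets = config.get("ctcf_offsets", _DEFAULT_CTCF_OFFSETS)
    sites = [CTCFSite(promoter + off, ori) for off, ori in ctcf_offsets]
    for s in sites:
        if not region.contains(s.pos):
            raise ConfigurationError(f"CTCF site at {s.pos} outside region")
    pen = landmarks["Pen"]
    frag = GenomicInterval(chrom, pen, pen + _PEN_FRAGMENT_LEN - 1)
    return LandmarkMap(region=region, bin_size=bin_size, landmarks=landmarks,
                       ctcf_sites=sites, pen_fragment=frag)


@dataclass(frozen=True)
class SVOperation:
    """One structural-variant edit, in reference coordinates.

    kind "inversion"/"deletion": ``interval`` is the affected reference
    interval. kind "insertion": ``interval`` is the source fragment (reference
    coordinates) and ``dest`` the reference position the fragment is inserted
    in front of.
    """

    kind: str
    interval: GenomicInterval
    dest: int | None = None

    def __post_init__(self):
        if self.kind not in ("inversion", "deletion", "insertion"):
            raise ConfigurationError(f"unknown SV operation kind {self.kind!r}")
        if self.kind == "insertion" and self.dest is None:
            raise ConfigurationError("insertion requires a destination position")


@dataclass
class AlleleSpec:
    """A named allele: ordered SV operations applied to the reference."""

    name: str
    operations: list[SVOperation] = field(default_factory=list)
    note: str = ""
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Segment engine: an allele is an ordered list of oriented reference segments.

@dataclass(frozen=True)
class _Segment:
    ref_start: int
    ref_end: int  # inclusive
    strand: int   # +1 or -1

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start + 1


def _split_at(segments: list[_Segment], ref_pos: int) -> list[_Segment]:
    """Split segments so that ``ref_pos`` starts a segment wherever covered."""
    out = []
    for s in segments:
        if s.ref_start < ref_pos <= s.ref_end:
            out.append(_Segment(s.ref_start, ref_pos - 1, s.strand))
            out.append(_Segment(ref_pos, s.ref_end, s.strand))
        else:
            out.append(s)
    return out


def _apply_operation(segments: list[_Segment], op: SVOperation) -> list[_Segment]:
    iv = op.interval
    if op.kind in ("inversion", "deletion"):
        segments = _split_at(segments, iv.start)
        segments = _split_at(segments, iv.end + 1)
        inside = [k for k, s in enumerate(segments)
                  if iv.start <= s.ref_start and s.ref_end <= iv.end]
        if not inside:
            raise ConfigurationError(
                f"{op.kind} interval {iv.start}-{iv.end} covers no material")
        if inside != list(range(inside[0], inside[-1] + 1)):
            raise ConfigurationError(
                f"{op.kind} interval {iv.start}-{iv.end} is not contiguous "
                "in the current allele")
        if op.kind == "deletion":
            return segments[:inside[0]] + segments[inside[-1] + 1:]
        block = [_Segment(s.ref_start, s.ref_end, -s.strand)
                 for s in reversed(segments[inside[0]:inside[-1] + 1])]
        return segments[:inside[0]] + block + segments[inside[-1] + 1:]
    # insertion
    segments = _split_at(segments, op.dest)
    idx = next((k for k, s in enumerate(segments) if s.ref_start == op.dest
                and s.strand == 1), None)
    if idx is None:
        raise ConfigurationError(
            f"insertion destination {op.dest} not at an available boundary")
    frag = _Segment(iv.start, iv.end, 1)
    return segments[:idx] + [frag] + segments[idx:]


def _allele_segments(allele: AlleleSpec, region: GenomicInterval) -> list[_Segment]:
    segments = [_Segment(region.start, region.end, 1)]
    for op in allele.operations:
        segments = _apply_operation(segments, op)
    return segments


def _allele_length(allele: AlleleSpec, region: GenomicInterval) -> int:
    return sum(s.length for s in _allele_segments(allele, region))


def liftover_point(pos: int, allele: AlleleSpec,
                   region: GenomicInterval | None = None) -> int:
    """Map a position in allele coordinates to reference coordinates.

    The allele coordinate space starts at ``region.start`` and runs over the
    allele's material in order. The map is total on the allele (every allele
    base derives from some reference base) and bijective outside deletions.
    An inversion of ``[a, b]`` maps ``pos`` within it to ``a + b - pos``.
    """
    if region is None:
        region = GenomicInterval(*DEFAULT_REGION)
    segments = _allele_segments(allele, region)
    offset = pos - region.start
    if offset < 0:
        raise MappingError(f"position {pos} precedes the allele start")
    for s in segments:
        if offset < s.length:
            if s.strand == 1:
                return s.ref_start + offset
            return s.ref_end - offset
        offset -= s.length
    raise MappingError(f"position {pos} beyond the allele end")


def position_in_allele(ref_pos: int, allele: AlleleSpec,
                       region: GenomicInterval | None = None) -> int:
    """Map a reference position into allele coordinates (inverse liftover).

    Raises :class:`MappingError` for positions whose material was deleted
    from the allele, naming the position.
    """
    if region is None:
        region = GenomicInterval(*DEFAULT_REGION)
    segments = _allele_segments(allele, region)
    cursor = region.start
    for s in segments:
        if s.ref_start <= ref_pos <= s.ref_end:
            if s.strand == 1:
                return cursor + (ref_pos - s.ref_start)
            return cursor + (s.ref_end - ref_pos)
        cursor += s.length
    raise MappingError(
        f"reference position {ref_pos} has no image in allele "
        f"{allele.name!r}: the material was deleted")


def interval_in_allele(iv: GenomicInterval, allele: AlleleSpec,
                       region: GenomicInterval | None = None) -> GenomicInterval:
    """Map a reference interval into allele coordinates.

    The interval must lie within a single (unbroken) segment of the allele, so
    the image is again a contiguous interval; otherwise a MappingError is
    raised.
    """
    a = position_in_allele(iv.start, allele, region)
    b = position_in_allele(iv.end, allele, region)
    lo, hi = min(a, b), max(a, b)
    if hi - lo != iv.end - iv.start:
        raise MappingError(
            f"interval {iv.start}-{iv.end} is split by allele {allele.name!r}")
    return GenomicInterval(iv.chrom, lo, hi, assembly_tag=allele.name)


def allele_bin_map(allele: AlleleSpec, region: GenomicInterval,
                   bin_size: int) -> np.ndarray:
    """Reference bin index for every allele bin.

    Requires every SV breakpoint to be bin-aligned (each allele bin then maps
    wholly into one reference bin); raises ConfigurationError otherwise.
    """
    segments = _allele_segments(allele, region)
    cursor = 0
    for s in segments:
        if cursor % bin_size != 0 or s.length % bin_size != 0 \
                or (s.ref_start - region.start) % bin_size != 0:
            raise ConfigurationError(
                f"allele {allele.name!r} has a breakpoint off the {bin_size}-bp "
                "bin grid; re-snap the SV operations to bin boundaries")
        cursor += s.length
    n_allele = cursor // bin_size
    out = np.empty(n_allele, dtype=np.int64)
    k = 0
    for s in segments:
        nb = s.length // bin_size
        first_ref_bin = (s.ref_start - region.start) // bin_size
        bins = np.arange(first_ref_bin, first_ref_bin + nb)
        if s.strand == -1:
            bins = bins[::-1]
        out[k:k + nb] = bins
        k += nb
    return out


def remap_matrix(values: np.ndarray, bin_map: np.ndarray,
                 n_ref: int) -> np.ndarray:
    """Accumulate an allele-coordinate matrix onto the reference bin grid.

    Output entry (i', j') sums all allele entries whose bins map there, so the
    total is conserved exactly; symmetry of the input is preserved because the
    remapping acts identically on rows and columns.
    """
    n = values.shape[0]
    if values.shape != (n, n) or bin_map.shape != (n,):
        raise ConfigurationError("matrix and bin map sizes disagree")
    out = np.zeros((n_ref, n_ref), dtype=values.dtype)
    np.add.at(out, (bin_map[:, None], bin_map[None, :]), values)
    return out


# ---------------------------------------------------------------------------
# Allele presets

def allele_presets(landmarks: LandmarkMap) -> dict[str, AlleleSpec]:
    """The six study alleles: wildtype, two inversions, three relocations.

    Inversions carry the Pen enhancer to the RA4 / PDE positions; relocations
    move the Pen fragment alone (deletion at source, insertion at destination)
    on a Pen-deleted background, to RA4, PDE, and just upstream of the
    promoter. Breakpoints are snapped to the bin grid; the reported
    (publication-scale) enhancer-promoter distances and CTCF counts are kept
    in ``metadata`` and are the calibration anchors for the proportion model.
    """
    region = landmarks.region
    chrom = region.chrom
    P = landmarks.landmarks["P"]
    frag = landmarks.pen_fragment
    B = landmarks.bin_size

    def snap(pos):  # snap down to a bin start
        return region.start + ((pos - region.start) // B) * B

    ra4_bin_start = snap(landmarks.landmarks["RA4"])
    pde_bin_start = snap(landmarks.landmarks["PDE"])

    presets = {}
    presets["WT"] = AlleleSpec(
        "WT", [], note="unrearranged reference locus",
        metadata={"reported_distance_bp": 400_000, "reported_p": 0.0})
    presets["Inv1"] = AlleleSpec(
        "Inv1",
        [SVOperation("inversion",
                     GenomicInterval(chrom, ra4_bin_start, frag.end))],
        note=("inversion swapping Pen and RA4 positions; reported as a 113-kb "
              "inversion with 6.4% reporter-positive forelimb cells"),
        metadata={"reported_distance_bp": 225_000, "reported_p": 0.064})
    presets["Inv2"] = AlleleSpec(
        "Inv2",
        [SVOperation("inversion",
                     GenomicInterval(chrom, pde_bin_start, frag.end))],
        note=("inversion carrying Pen to the PDE position; reported as a "
              "204-kb inversion with 27% reporter-positive cells"),
        metadata={"reported_distance_bp": 116_000, "reported_p": 0.27})
    presets["DelPen"] = AlleleSpec(
        "DelPen", [SVOperation("deletion", frag)],
        note="Pen-deleted background of the relocation alleles",
        metadata={})
    rel_note = ("Pen fragment relocation on the Pen-deleted background "
                "(deletion at source + insertion at destination)")
    presets["Rel1"] = AlleleSpec(
        "Rel1",
        [SVOperation("deletion", frag),
         SVOperation("insertion", frag, dest=ra4_bin_start)],
        note=rel_note + "; inserted at RA4, reported 216 kb from the promoter "
             "with 2% reporter-positive cells",
        metadata={"reported_distance_bp": 216_000, "reported_p": 0.02})
    presets["Rel2"] = AlleleSpec(
        "Rel2",
        [SVOperation("deletion", frag),
         SVOperation("insertion", frag, dest=pde_bin_start)],
        note=rel_note + "; inserted at PDE, reported 125 kb from the promoter "
             "with 59% reporter-positive cells",
        metadata={"reported_distance_bp": 125_000, "reported_p": 0.59})
    # Insertion upstream of the promoter shifts the promoter itself by the
    # fragment length; this destination leaves a 5-kb gap between fragment
    # end and promoter in allele coordinates (centre distance ~10 kb,
    # matching the reported 10.5-kb enhancer-promoter spacing).
    rel3_dest = snap(P - 5_000)
    presets["Rel3"] = AlleleSpec(
        "Rel3",
        [SVOperation("deletion", frag),
         SVOperation("insertion", frag, dest=rel3_dest)],
        note=rel_note + "; inserted just upstream of the promoter (reported "
             "insertion offset 7.7 kb, enhancer-promoter distance 10.5 kb) "
             "with 62% reporter-positive cells",
        metadata={"reported_distance_bp": 10_500, "reported_p": 0.62,
                  "reported_insertion_offset_bp": 7_700})
    return presets


def pen_anchor_in_allele(allele: AlleleSpec,
                         landmarks: LandmarkMap) -> GenomicInterval:
    """The mobilised Pen fragment's interval in allele coordinates."""
    return interval_in_allele(landmarks.pen_fragment, allele, landmarks.region)


def pen_promoter_distance(allele: AlleleSpec, landmarks: LandmarkMap) -> int:
    """Geometric promoter-to-Pen distance (bp) in allele coordinates.

    Measured centre-to-centre between the promoter and the mobilised
    enhancer fragment.
    """
    region = landmarks.region
    p_allele = position_in_allele(landmarks.landmarks["P"], allele, region)
    frag = pen_anchor_in_allele(allele, landmarks)
    centre = (frag.start + frag.end) // 2
    return abs(centre - p_allele)


def ctcf_between_pen_and_promoter(allele: AlleleSpec,
                                  landmarks: LandmarkMap) -> int:
    """Number of CTCF sites strictly between promoter and Pen in the allele.

    Sites deleted by the allele are skipped; orientations are recorded in the
    landmark map but only the count enters the insulation/proportion models.
    """
    region = landmarks.region
    p_allele = position_in_allele(landmarks.landmarks["P"], allele, region)
    frag = pen_anchor_in_allele(allele, landmarks)
    centre = (frag.start + frag.end) // 2
    lo, hi = min(p_allele, centre), max(p_allele, centre)
    n = 0
    for site in landmarks.ctcf_sites:
        try:
            sp = position_in_allele(site.pos, allele, region)
        except MappingError:
            continue
        if lo < sp < hi:
            n += 1
    return n
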