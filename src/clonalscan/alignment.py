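"""Core-genome alignment handling: SNP calling, divergence, windows.

The alignment is a haploid multi-strain whole-genome alignment (one aligned
sequence per strain, equal lengths) with a designated ingroup, a single
outgroup strain, and a reference strain whose gap-free positions define the
coordinate system for windows and reports.

Definitions used throughout:

* core column — an alignment column with no gap and no ambiguity (``N``) in
  any ingroup strain;
* polymorphic column — a core column at which the ingroup carries >= 2
  alleles;
* divergent column — a core column at which the outgroup carries a real
  nucleotide that matches none of the ingroup alleles.  A column can be both
  polymorphic and divergent; it then contributes to both counters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import AlignIO

# Nucleotide codes used in the packed alignment matrix.
A, C, G, T, GAP, NN = 0, 1, 2, 3, 4, 5
ALPHABET = "ACGT-N"
_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
_ENCODE = np.full(256, NN, dtype=np.uint8)
for _i, _ch in enumerate(ALPHABET):
    _ENCODE[ord(_ch)] = _i
    _ENCODE[ord(_ch.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Pack an IUPAC string into uint8 codes (unknown letters become N)."""
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    return _ENCODE[raw]


def decode_sequence(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


class AlignmentFormatError(ValueError):
    """Raised when the input alignment violates the expected format."""


@dataclass
class AlignmentMatrix:
    """Packed multi-strain alignment with a reference coordinate map.

    Attributes
    ----------
    ids : list of str
        All strain identifiers, ingroup plus the outgroup, in matrix row
        order.
    data : uint8 array, shape (n_strains, n_columns)
        Encoded alignment (A=0 C=1 G=2 T=3 '-'=4 N=5).
    reference_id, outgroup_id : str
        The coordinate reference (must be an ingroup strain) and the single
        outgroup strain.
    """

    ids: list[str]
    data: np.ndarray
    reference_id: str
    outgroup_id: str
    ref_coords: np.ndarray = field(init=False, repr=False)
    col_of_ref: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[0] != len(self.ids):
            raise AlignmentFormatError("matrix shape does not match strain ids")
        for name, sid in (("reference", self.reference_id), ("outgroup", self.outgroup_id)):
            if sid not in self.ids:
                raise KeyError(f"{name} strain {sid!r} not present in alignment")
        if self.reference_id == self.outgroup_id:
            raise AlignmentFormatError("reference strain must be an ingroup strain")
        ref_row = self.data[self.ids.index(self.reference_id)]
        is_ref_base = ref_row < GAP
        # column -> 0-based reference coordinate; -1 where the reference is gapped
        coords = np.cumsum(is_ref_base) - 1
        coords[~is_ref_base] = -1
        self.ref_coords = coords
        self.col_of_ref = np.flatnonzero(is_ref_base)

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    @property
    def reference_length(self) -> int:
        """Number of non-gap reference positions (the coordinate span)."""
        return int(self.col_of_ref.size)

    @property
    def ingroup_ids(self) -> list[str]:
        return [s for s in self.ids if s != self.outgroup_id]

    @property
    def ingroup_rows(self) -> np.ndarray:
        idx = [i for i, s in enumerate(self.ids) if s != self.outgroup_id]
        return self.data[idx]

    @property
    def outgroup_row(self) -> np.ndarray:
        return self.data[self.ids.index(self.outgroup_id)]

    def row(self, strain_id: str) -> np.ndarray:
        return self.data[self.ids.index(strain_id)]

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.ids, self.data):
                fh.write(f">{sid}\n{decode_sequence(row)}\n")


def read_alignment(path: str | Path, reference_id: str, outgroup_id: str) -> AlignmentMatrix:
    """Read an aligned multi-FASTA into an :class:`AlignmentMatrix`.

    All records must have equal aligned length; ``reference_id`` and
    ``outgroup_id`` must both be present.
    """
    try:
        aln = AlignIO.read(str(path), "fasta")
    except ValueError as exc:  # unequal lengths or empty file
        raise AlignmentFormatError(f"{path}: {exc}") from exc
    ids = [rec.id for rec in aln]
    data = np.stack([encode_sequence(str(rec.seq)) for rec in aln])
    return AlignmentMatrix(ids=ids, data=data, reference_id=reference_id, outgroup_id=outgroup_id)


@dataclass
class SnpRecord:
    """One variant alignment column (ingroup-polymorphic and/or divergent)."""

    ref_pos: int                 # 0-based reference coordinate
    column: int                  # alignment column index
    alleles: str                 # one character per ingroup strain, matrix order
    outgroup_allele: str         # 'A'..'T', or '-'/'N' when absent
    n_alleles: int               # distinct real nucleotides among the ingroup
    is_polymorphic: bool
    is_divergent: bool
    ancestral: Optional[str]     # outgroup-polarised ancestral allele, else None
    clonal_class: str = "unclassified"   # clonal | recombinant | excluded
    pattern: Optional[object] = None     # SitePattern set by the classifier


def extract_core_and_snps(matrix: AlignmentMatrix) -> tuple[list[SnpRecord], np.ndarray]:
    """Call core columns and variant columns.

    Returns ``(snps, core_mask)`` where ``core_mask`` is a boolean array over
    alignment columns.  A :class:`SnpRecord` is emitted for every core column
    that is ingroup-polymorphic or divergent from the outgroup; columns where
    the reference itself is gapped carry ``ref_pos = -1`` and are excluded
    from windowed reports.
    """
    ingroup = matrix.ingroup_rows
    outgroup = matrix.outgroup_row
    core = np.all(ingroup < GAP, axis=0)

    # per-base ingroup occupancy, shape (4, L)
    counts = np.stack([(ingroup == b).sum(axis=0) for b in range(4)])
    present = counts > 0
    n_alleles = present.sum(axis=0)
    poly = core & (n_alleles >= 2)
    out_real = outgroup < GAP
    out_code = np.where(out_real, outgroup, 0)
    out_matches = present[out_code, np.arange(matrix.n_columns)] & out_real
    divergent = core & out_real & ~out_matches

    snps: list[SnpRecord] = []
    for col in np.flatnonzero(poly | divergent):
        col = int(col)
        alleles = decode_sequence(ingroup[:, col])
        out_ch = ALPHABET[outgroup[col]]
        ancestral = out_ch if (out_real[col] and out_matches[col]) else None
        snps.append(
            SnpRecord(
                ref_pos=int(matrix.ref_coords[col]),
                column=col,
                alleles=alleles,
                outgroup_allele=out_ch,
                n_alleles=int(n_alleles[col]),
                is_polymorphic=bool(poly[col]),
                is_divergent=bool(divergent[col]),
                ancestral=ancestral,
            )
        )
    return snps, core


@dataclass
class WindowRow:
    """Per-window counts over reference coordinates (0-based half-open)."""

    index: int
    start: int
    end: int
    core_sites: int
    gap_total: int
    analyzed: bool
    n_polymorphic: int = 0
    n_polymorphic_corrected: float = 0.0
    correction_defined: bool = True
    n_divergent: int = 0
    n_recombinant: Optional[int] = None
    n_clonal: Optional[int] = None
    n_excluded: Optional[int] = None
    recombinant_proportion: Optional[float] = None
    n_unique_topologies: Optional[int] = None
    unique_topologies_per_snp: Optional[float] = None
    poly_band: Optional[str] = None      # low | within | high
    div_band: Optional[str] = None
    recomb_band: Optional[str] = None

    @property
    def width(self) -> int:
        return self.end - self.start


def back_mutation_multiplier(d: float) -> float:
    """Jukes–Cantor multiple-hit multiplier from per-window divergence ``d``.

    The observed divergent fraction ``d`` underestimates the substitution
    load by the factor ``(-3/4 ln(1 - 4d/3)) / d`` (1 at d=0); undefined for
    ``d >= 3/4`` (saturation).
    """
    if d < 0:
        raise ValueError("divergence fraction must be non-negative")
    if d == 0:
        return 1.0
    if d >= 0.75:
        raise ValueError("divergence at or beyond Jukes-Cantor saturation (d >= 3/4)")
    return float(-0.75 * np.log1p(-4.0 * d / 3.0) / d)


def back_mutation_correction(window: WindowRow) -> WindowRow:
    """Fill the back-mutation-corrected polymorphism count for one window.

    Uses the window's own divergent-site rate as the multiple-hit rate
    estimate.  At saturation the window is flagged and the raw count kept.
    """
    if not window.analyzed or window.core_sites <= 0:
        window.n_polymorphic_corrected = float(window.n_polymorphic)
        return window
    d = window.n_divergent / window.core_sites
    try:
        m = back_mutation_multiplier(d)
    except ValueError:
        window.correction_defined = False
        window.n_polymorphic_corrected = float(window.n_polymorphic)
        return window
    window.n_polymorphic_corrected = window.n_polymorphic * m
    return window


def make_windows(
    matrix: AlignmentMatrix,
    snps: Sequence[SnpRecord],
    core_mask: np.ndarray,
    window_bp: int = 10_000,
    gap_cap_bp: int = 5_000,
    exclude_intervals: Iterable[tuple[int, int]] = (),
) -> list[WindowRow]:
    """Tile reference coordinates into fixed windows and count per window.

    A window is not analyzed when its non-core (gap/ambiguous) column total
    strictly exceeds ``gap_cap_bp``, when it overlaps a configured exclusion
    interval, or when it is a trailing partial window narrower than half the
    window width.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    n_ref = matrix.reference_length
    core_at_ref = core_mask[matrix.col_of_ref]          # core status per reference position
    excl = list(exclude_intervals)

    n_windows = int(np.ceil(n_ref / window_bp)) if n_ref else 0
    windows = []
    for w in range(n_windows):
        start, end = w * window_bp, min((w + 1) * window_bp, n_ref)
        core_sites = int(core_at_ref[start:end].sum())
        gap_total = (end - start) - core_sites
        analyzed = gap_total <= gap_cap_bp
        if end - start < window_bp and (end - start) < window_bp / 2:
            analyzed = False
        if any(s < end and start < e for s, e in excl):
            analyzed = False
        windows.append(
            WindowRow(index=w, start=start, end=end, core_sites=core_sites,
                      gap_total=gap_total, analyzed=analyzed)
        )

    for snp in snps:
        if snp.ref_pos < 0:
            continue
        row = windows[snp.ref_pos // window_bp]
        if snp.is_polymorphic:
            row.n_polymorphic += 1
        if snp.is_divergent:
            row.n_divergent += 1
    for row in windows:
        back_mutation_correction(row)
    return windows
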