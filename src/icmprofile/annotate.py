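"""Proteoform / peptidoform annotation by average [M+H]+ mass.

Observed peak bins are matched against a tabular database of molecular forms
whose theoretical average [M+H]+ masses are either supplied directly or
derived from an amino-acid sequence plus a signed PTM mass shift.  Matching
uses a relative mass tolerance (default 0.05%, i.e. +/- 500 ppm), the
accuracy a lock-mass-corrected linear-mode TOF can hold over this range.

Average (not monoisotopic) masses are the default because linear-mode
profiles of intact biomolecules do not resolve isotopes; a monoisotopic
residue table is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FeatureMatrix, PipelineError

# IUPAC average residue masses (Da), 4 decimals.
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

# Monoisotopic residue masses (Da), for the optional monoisotopic mode.
MONOISOTOPIC_RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406,
    "N": 114.04293, "D": 115.02694, "Q": 128.05858, "K": 128.09496,
    "E": 129.04259, "M": 131.04049, "H": 137.05891, "F": 147.06841,
    "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

WATER_AVERAGE = 18.0153
WATER_MONO = 18.010565
PROTON = 1.00728

DEFAULT_TOLERANCE_PPM = 500.0  # <= 0.05% relative


def average_mh_from_sequence(
    sequence: str, ptm_shift: float = 0.0, monoisotopic: bool = False
) -> float:
    """Theoretical [M+H]+ of a peptide/protein sequence plus a PTM shift.

    Sum of residue masses + water + one proton + ``ptm_shift`` (signed Da).
    """
    if not sequence:
        raise PipelineError("empty sequence")
    table = MONOISOTOPIC_RESIDUE_MASS if monoisotopic else AVERAGE_RESIDUE_MASS
    water = WATER_MONO if monoisotopic else WATER_AVERAGE
    total = 0.0
    for pos, aa in enumerate(sequence):
        try:
            total += table[aa]
        except KeyError:
            raise PipelineError(
                f"unknown residue {aa!r} at position {pos + 1} of sequence"
            ) from None
    return total + water + PROTON + ptm_shift


@dataclass
class ProteoformRecord:
    """A database entry: one molecular form with its theoretical [M+H]+."""

    id: str
    gene: str = ""
    description: str = ""
    sequence: str = ""
    ptm_shift: float = 0.0
    theoretical_avg_mh: float | None = None

    def __post_init__(self) -> None:
        if self.theoretical_avg_mh is None:
            if not self.sequence:
                raise PipelineError(
                    f"record {self.id}: needs a theoretical mass or a sequence"
                )
            self.theoretical_avg_mh = average_mh_from_sequence(
                self.sequence, self.ptm_shift
            )
        if self.theoretical_avg_mh <= 0:
            raise PipelineError(f"record {self.id}: non-positive theoretical mass")
        if self.sequence:
            derived = average_mh_from_sequence(self.sequence, self.ptm_shift)
            if abs(derived - self.theoretical_avg_mh) > 0.01:
                raise PipelineError(
                    f"record {self.id}: stored mass {self.theoretical_avg_mh:.4f} "
                    f"disagrees with sequence-derived {derived:.4f}"
                )


@dataclass(frozen=True)
class AnnotationHit:
    """One bin-to-record match within tolerance."""

    bin_mz: float
    record_id: str
    ppm_error: float  # signed: (observed - theoretical) / theoretical * 1e6
    rank: int


def match_peaks_to_db(
    m: FeatureMatrix | np.ndarray,
    db: list[ProteoformRecord],
    tolerance_ppm: float = DEFAULT_TOLERANCE_PPM,
) -> tuple[list[AnnotationHit], list[float]]:
    """Match observed bins to database records within a relative tolerance.

    For each bin, every record with ``|observed - theoretical| / theoretical
    <= tolerance`` is returned, ranked by increasing absolute ppm error (ties
    broken by record id).  Bins with no hit are returned in the unannotated
    list — the expected common case for an incompletely characterized
    proteome.
    """
    if not db:
        raise PipelineError("empty proteoform database")
    if tolerance_ppm <= 0:
        raise PipelineError("tolerance must be > 0")
    bins = m.bins if isinstance(m, FeatureMatrix) else np.asarray(m, dtype=float)
    hits: list[AnnotationHit] = []
    unannotated: list[float] = []
    for b in bins:
        cand = []
        for rec in db:
            theo = rec.theoretical_avg_mh
            ppm = (b - theo) / theo * 1e6
            if abs(ppm) <= tolerance_ppm:
                cand.append((abs(ppm), rec.id, ppm))
        if not cand:
            unannotated.append(float(b))
            continue
        cand.sort(key=lambda t: (t[0], t[1]))
        for rank, (_, rid, ppm) in enumerate(cand, start=1):
            hits.append(
                AnnotationHit(bin_mz=float(b), record_id=rid, ppm_error=float(ppm), rank=rank)
            )
    return hits, unannotated


def hits_to_frame(hits: list[AnnotationHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "bin_mz": h.bin_mz,
                "record_id": h.record_id,
                "ppm_error": h.ppm_error,
                "rank": h.rank,
            }
            for h in hits
        ],
        columns=["bin_mz", "record_id", "ppm_error", "rank"],
    )


def read_proteoform_db(path) -> list[ProteoformRecord]:
    """Read a proteoform database TSV: id, gene, description, sequence,
    ptm_shift, theoretical_avg_mh (empty mass -> derived from sequence)."""
    frame = pd.read_csv(path, sep="\t", comment="#", dtype={"id": str})

    def _s(value) -> str:
        return "" if pd.isna(value) else str(value)

    records = []
    for _, row in frame.iterrows():
        mass = row.get("theoretical_avg_mh")
        shift = row.get("ptm_shift", 0.0)
        records.append(
            ProteoformRecord(
                id=str(row["id"]),
                gene=_s(row.get("gene")),
                description=_s(row.get("description")),
                sequence=_s(row.get("sequence")),
                ptm_shift=0.0 if pd.isna(shift) else float(shift),
                theoretical_avg_mh=float(mass) if pd.notna(mass) else None,
            )
        )
    return records


def write_proteoform_db(records: list[ProteoformRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "id": r.id,
                "gene": r.gene,
                "description": r.description,
                "sequence": r.sequence,
                "ptm_shift": r.ptm_shift,
                "theoretical_avg_mh": r.theoretical_avg_mh,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)
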