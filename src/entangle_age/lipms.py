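"""LiP-MS peptide evidence: significance calls and cleavage-site mapping.

Limited proteolysis mass spectrometry reports tryptic and half-tryptic
peptides whose abundance differs between aged and young cells.  A
half-tryptic peptide has one terminus generated by proteinase K, which
localizes the conformational change; for tryptic peptides the central
residue is used as a proxy.  A protein "exhibits an age-associated
structural change" when at least one of its peptides is significant
(|fold change| > 5 and adjusted p < 0.05, both strict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PeptideRecord",
    "CleavageSite",
    "read_peptide_table",
    "records_from_frame",
    "is_significant",
    "classify_protein_change",
    "map_cleavage_site",
    "residue_alteration_mask",
    "protein_change_table",
]

BUFFER = 3  # +/- residues around an altered cleavage site


@dataclass(frozen=True)
class PeptideRecord:
    protein: str
    start: int
    end: int
    kind: str  # "tryptic" | "half_tryptic"
    pk_terminus: str = "none"  # "start" | "end" | "none"
    fold_change: float = 0.0
    adj_p: float = 1.0

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("start > end")
        if self.kind == "tryptic" and self.pk_terminus != "none":
            raise ValueError("tryptic peptide cannot have a PK terminus")
        if self.kind == "half_tryptic" and self.pk_terminus == "none":
            raise ValueError("half-tryptic peptide requires a PK terminus")


@dataclass(frozen=True)
class CleavageSite:
    protein: str
    residue: int
    buffered_set: frozenset

    @staticmethod
    def at(protein: str, residue: int, length: int | None = None,
           buffer: int = BUFFER) -> "CleavageSite":
        lo = max(1, residue - buffer)
        hi = residue + buffer if length is None else min(length, residue + buffer)
        return CleavageSite(protein, residue, frozenset(range(lo, hi + 1)))


def read_peptide_table(path, sep: str = "\t", log2_fold_change: bool = False
                       ) -> list:
    """Read a peptide table (columns: protein, start, end, kind,
    pk_terminus, fold_change, adj_p).  With ``log2_fold_change`` the
    stored column is interpreted as log2 and converted to a linear ratio
    before thresholding."""
    df = pd.read_csv(path, sep=sep)
    return records_from_frame(df, log2_fold_change=log2_fold_change)


def records_from_frame(df: pd.DataFrame, log2_fold_change: bool = False) -> list:
    recs = []
    for row in df.itertuples(index=False):
        fc = float(row.fold_change)
        if log2_fold_change:
            fc = float(np.sign(fc) or 1.0) * 2.0 ** abs(fc)
        recs.append(
            PeptideRecord(
                protein=str(row.protein),
                start=int(row.start),
                end=int(row.end),
                kind=str(row.kind),
                pk_terminus=str(getattr(row, "pk_terminus", "none")),
                fold_change=fc,
                adj_p=float(row.adj_p),
            )
        )
    return recs


def is_significant(peptide: PeptideRecord, fc_threshold: float = 5.0,
                   alpha: float = 0.05) -> bool:
    """Strict thresholds: |fold change| > fc_threshold AND adj_p < alpha."""
    if peptide.adj_p is None or np.isnan(peptide.adj_p):
        raise ValueError("missing adjusted p-value")
    return abs(peptide.fold_change) > fc_threshold and peptide.adj_p < alpha


def classify_protein_change(peptides, fc_threshold: float = 5.0,
                            alpha: float = 0.05) -> bool:
    """Protein-level change call: any significant peptide.

    Zero observed peptides means "not observed" and raises, distinct
    from an observed protein with no significant peptide (False).
    """
    peptides = list(peptides)
    if not peptides:
        raise ValueError("protein has no observed peptides")
    return any(is_significant(p, fc_threshold, alpha) for p in peptides)


def map_cleavage_site(peptide: PeptideRecord, length: int | None = None,
                      buffer: int = BUFFER) -> CleavageSite:
    """Altered-cleavage residue of a significant peptide.

    Half-tryptic: the proteinase-K-generated terminus.  Tryptic: the
    central residue, floor((start+end)/2) for even-length spans.  The
    ±buffer window is clipped to [1, length].
    """
    if peptide.kind == "half_tryptic":
        residue = peptide.start if peptide.pk_terminus == "start" else peptide.end
    else:
        residue = (peptide.start + peptide.end) // 2
    return CleavageSite.at(peptide.protein, residue, length, buffer)


def residue_alteration_mask(length: int, sites) -> np.ndarray:
    """Boolean mask over residues 1..length: union of buffered sites."""
    mask = np.zeros(length, dtype=bool)
    for site in sites:
        idx = np.array(sorted(r for r in site.buffered_set if 1 <= r <= length))
        if len(idx):
            mask[idx - 1] = True
    return mask


def protein_change_table(
    peptides,
    lengths: dict | None = None,
    fc_threshold: float = 5.0,
    alpha: float = 0.05,
    buffer: int = BUFFER,
) -> pd.DataFrame:
    """Per-protein change classification and altered residue sets.

    Returns a frame with columns protein, changed, n_peptides,
    n_significant, altered_residues (sorted residue list from buffered
    cleavage sites).  Peptides extending past the known protein length
    (structure/sequence version mismatch) are dropped with a warning.
    """
    by_protein: dict = {}
    for p in peptides:
        if lengths is not None and p.protein in lengths and p.end > lengths[p.protein]:
            warnings.warn(f"peptide {p.protein}:{p.start}-{p.end} outside chain; dropped")
            continue
        by_protein.setdefault(p.protein, []).append(p)
    rows = []
    for protein, recs in by_protein.items():
        sig = [p for p in recs if is_significant(p, fc_threshold, alpha)]
        length = lengths.get(protein) if lengths else None
        sites = [map_cleavage_site(p, length, buffer) for p in sig]
        altered = sorted(set().union(*[s.buffered_set for s in sites])) if sites else []
        rows.append(
            {
                "protein": protein,
                "changed": bool(sig),
                "n_peptides": len(recs),
                "n_significant": len(sig),
                "altered_residues": altered,
            }
        )
    return pd.DataFrame(rows)
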