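"""Sequence-motif analysis of module phosphosites.

Kinases prefer specific residues around the phosphoacceptor (e.g. the
proline-directed S/T-P of CDKs), so the amino acids flanking a module's
sites carry evidence about its regulator.  Fixed-width windows (default
15 residues: the modified site plus 7 on each side) are extracted from a
protein FASTA; windows running past a terminus are padded with '-'.
Per position offset and residue, enrichment and depletion of module
windows versus background windows are scored with one-sided Fisher's
exact tests; pad characters are excluded from the count tables since
they are non-observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

PAD = "-"
DEFAULT_FLANK = 7

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class FlankingPeptide:
    """A (2w+1)-residue window centered on a modified residue."""

    sequence: str
    site_key: tuple[str, str]  # (gene, site)

    @property
    def width(self) -> int:
        return (len(self.sequence) - 1) // 2

    @property
    def center(self) -> str:
        return self.sequence[self.width]


def read_fasta(path) -> dict[str, str]:
    """Load a protein FASTA as id -> sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def extract_window(sequence: str, position: int, w: int = DEFAULT_FLANK) -> str:
    """Window of ``w`` residues either side of 1-based ``position``,
    edge-padded with '-'."""
    if not 1 <= position <= len(sequence):
        raise ValueError(
            f"position {position} outside sequence of length {len(sequence)}"
        )
    i = position - 1
    left = sequence[max(0, i - w): i]
    right = sequence[i + 1: i + 1 + w]
    return PAD * (w - len(left)) + left + sequence[i] + right + PAD * (w - len(right))


def collect_flanking_sequences(
    mapping: pd.DataFrame,
    fasta: Mapping[str, str],
    labels: pd.Series,
    w: int = DEFAULT_FLANK,
) -> dict[int, list[FlankingPeptide]]:
    """Extract flanking windows for every mapped site, grouped by module.

    ``mapping`` has columns gene, site, protein_id, positions (list of
    1-based ordinals; multiply-phosphorylated sites yield one window per
    position).  ``labels`` maps (gene, site) to a module id (-1 noise).
    Sites whose protein is missing from the FASTA are skipped and
    reported; a position beyond the sequence is an error naming the site.
    """
    modules: dict[int, list[FlankingPeptide]] = {}
    skipped: list[tuple[str, str]] = []
    label_map = dict(labels.items())
    for _, row in mapping.iterrows():
        key = (row["gene"], row["site"])
        if key not in label_map:
            continue
        module = int(label_map[key])
        seq = fasta.get(row["protein_id"])
        if seq is None:
            skipped.append(key)
            continue
        for pos in row["positions"]:
            try:
                window = extract_window(seq, pos, w)
            except ValueError as exc:
                raise ValueError(
                    f"site {row['gene']} {row['site']}: {exc}"
                ) from None
            modules.setdefault(module, []).append(FlankingPeptide(window, key))
    if skipped:
        warnings.warn(
            f"{len(skipped)} site(s) skipped; protein id absent from FASTA"
        )
    return modules


def calculate_motif_enrichment(
    module_peptides: Sequence[FlankingPeptide],
    background_peptides: Sequence[FlankingPeptide],
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-(offset, residue) Fisher enrichment and depletion p-values.

    For each position offset in [-w, +w] and amino acid, a 2x2 table
    counts (module vs background) x (that residue vs any other residue)
    over non-pad characters at that offset.  One-sided p-values are
    reported for enrichment ("greater") and depletion ("less").  With
    ``adjust`` the enrichment p's get a BH correction across all
    (offset, residue) cells.
    """
    if not module_peptides or not background_peptides:
        raise ValueError("module and background peptide lists must be non-empty")
    overlap = {p.sequence for p in module_peptides} & {
        p.sequence for p in background_peptides
    }
    w = module_peptides[0].width
    if any(p.width != w for p in list(module_peptides) + list(background_peptides)):
        raise ValueError("peptides have inconsistent window widths")

    records = []
    for offset in range(-w, w + 1):
        idx = offset + w
        mod_res = [p.sequence[idx] for p in module_peptides
                   if p.sequence[idx] != PAD]
        bg_res = [p.sequence[idx] for p in background_peptides
                  if p.sequence[idx] != PAD]
        n_mod, n_bg = len(mod_res), len(bg_res)
        if n_mod == 0 and n_bg == 0:
            continue
        for aa in AMINO_ACIDS:
            k_mod = mod_res.count(aa)
            k_bg = bg_res.count(aa)
            table = [[k_mod, n_mod - k_mod], [k_bg, n_bg - k_bg]]
            _, p_enrich = stats.fisher_exact(table, alternative="greater")
            _, p_deplete = stats.fisher_exact(table, alternative="less")
            records.append(
                (offset, aa, k_mod, n_mod, k_bg, n_bg,
                 float(p_enrich), float(p_deplete))
            )
    out = pd.DataFrame(
        records,
        columns=["offset", "residue", "module_count", "module_total",
                 "background_count", "background_total",
                 "enrichment_p", "depletion_p"],
    )
    if adjust and len(out):
        from .associations import benjamini_hochberg

        out["enrichment_adj_p"] = benjamini_hochberg(out["enrichment_p"].to_numpy())
        out["depletion_adj_p"] = benjamini_hochberg(out["depletion_p"].to_numpy())
    return out


def peptide_similarity_matrix(
    peptides: Sequence[FlankingPeptide],
) -> pd.DataFrame:
    """Count shared non-pad residues between every pair of windows.

    Entry (i, j) is the number of positions where windows i and j carry
    the same non-pad residue; the diagonal is each window's non-pad
    length.  Clustering this matrix exposes multiple sub-motifs within
    one module.
    """
    seqs = [p.sequence for p in peptides]
    if len(set(map(len, seqs))) > 1:
        raise ValueError("peptides must have equal length")
    arr = np.array([list(s) for s in seqs])
    n = len(seqs)
    sim = np.zeros((n, n), dtype=int)
    for i in range(n):
        same = (arr == arr[i]) & (arr[i] != PAD) & (arr != PAD)
        sim[i] = same.sum(axis=1)
    names = [f"{p.site_key[0]}_{p.site_key[1]}" for p in peptides]
    return pd.DataFrame(sim, index=names, columns=names)


def log10_p_grid(enrichment: pd.DataFrame, column: str = "enrichment_p") -> pd.DataFrame:
    """Pivot per-(offset, residue) p-values into a residue x offset grid
    of -log10(p) for heat-grid display or TSV export."""
    grid = enrichment.pivot(index="residue", columns="offset", values=column)
    return -np.log10(grid)
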