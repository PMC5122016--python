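"""Expected input molecules per gene in a diluted replicate.

A dilution replicate contains a known (estimated) mass of RNA.  Dividing
that mass by the average transcript mass — computed from the bulk
reference's expression-weighted average transcript length — gives the
total number of molecules in the tube; multiplying by each gene's relative
frequency in the bulk gives the gene's expected molecule count ``M_g``.
The targeted mass itself is anchored by ERCC spike-ins: the known spiked
mass divided by the fraction of reads assigned to spike-ins estimates the
total mass, and the remainder is the targeted (endogenous) mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Average molecular weight of one ssRNA nucleotide residue (g/mol) plus a
# 5' end correction for the terminal phosphate/hydroxyl arithmetic.
NT_MOLECULAR_WEIGHT = 320.5
END_CORRECTION = 159.0
AVOGADRO = 6.022e23

__all__ = [
    "BulkReference",
    "ErccPanel",
    "MoleculeExpectation",
    "rna_molecule_mass",
    "weighted_average_transcript_length",
    "estimate_targeted_mass",
    "expected_molecules",
    "ercc_expected_molecules",
    "ct_to_log10_molecules",
]


@dataclass
class BulkReference:
    """Per-gene relative frequencies plus transcript lengths from a bulk
    reference experiment (the "truth" transcriptome).

    ``isoforms`` may carry one row per isoform (gene_id, length_nt, weight);
    if absent, ``effective_length`` per gene is used directly.
    """

    gene_id: np.ndarray
    relative_frequency: np.ndarray
    effective_length: np.ndarray
    isoforms: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.gene_id = np.asarray(self.gene_id)
        self.relative_frequency = np.asarray(self.relative_frequency, dtype=float)
        self.effective_length = np.asarray(self.effective_length, dtype=float)
        if np.any(self.relative_frequency < 0):
            raise ValueError("relative frequencies must be non-negative")
        total = self.relative_frequency.sum()
        if not np.isclose(total, 1.0, atol=1e-9, rtol=0):
            raise ValueError(f"relative frequencies must sum to 1, got {total!r}")
        if np.any(self.effective_length < 1):
            raise ValueError("transcript lengths must be >= 1 nt")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BulkReference":
        return cls(
            gene_id=frame["gene_id"].to_numpy(),
            relative_frequency=frame["relative_frequency"].to_numpy(dtype=float),
            effective_length=frame["effective_length"].to_numpy(dtype=float),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_id,
                "relative_frequency": self.relative_frequency,
                "effective_length": self.effective_length,
            }
        )


@dataclass
class ErccPanel:
    """Spike-in panel: transcript ids, lengths, molar fractions and the
    spiked mass per sample (femtograms)."""

    transcript_id: np.ndarray
    length_nt: np.ndarray
    molar_fraction: np.ndarray
    mass_fg: float = 0.0

    def __post_init__(self) -> None:
        self.transcript_id = np.asarray(self.transcript_id)
        self.length_nt = np.asarray(self.length_nt, dtype=float)
        self.molar_fraction = np.asarray(self.molar_fraction, dtype=float)
        if not np.isclose(self.molar_fraction.sum(), 1.0, atol=1e-9, rtol=0):
            raise ValueError("molar fractions must sum to 1")
        if self.mass_fg < 0:
            raise ValueError("spiked mass must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "transcript_id": self.transcript_id,
                "length_nt": self.length_nt,
                "molar_fraction": self.molar_fraction,
                "mass_fg": self.mass_fg,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ErccPanel":
        mass = float(frame["mass_fg"].iloc[0]) if "mass_fg" in frame else 0.0
        return cls(
            transcript_id=frame["transcript_id"].to_numpy(),
            length_nt=frame["length_nt"].to_numpy(dtype=float),
            molar_fraction=frame["molar_fraction"].to_numpy(dtype=float),
            mass_fg=mass,
        )


@dataclass
class MoleculeExpectation:
    """Total and per-gene expected molecule counts in a diluted replicate."""

    targeted_mass_pg: float
    average_transcript_length_nt: float
    average_transcript_mass_pg: float
    total_molecules: float
    gene_id: np.ndarray
    expected_molecules: np.ndarray = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.gene_id, "expected_molecules": self.expected_molecules}
        )


def rna_molecule_mass(length_nt: float) -> float:
    """Mass in picograms of one single-stranded RNA molecule of the given
    length, from the average per-nucleotide molecular weight with a 5'-end
    correction, divided by Avogadro's number."""
    length_nt = np.asarray(length_nt, dtype=float)
    if np.any(length_nt <= 0):
        raise ValueError("transcript length must be positive")
    grams = (NT_MOLECULAR_WEIGHT * length_nt + END_CORRECTION) / AVOGADRO
    out = grams * 1e12  # g -> pg
    return float(out) if out.ndim == 0 else out


def weighted_average_transcript_length(
    lengths_nt, weights
) -> float:
    """Average transcript length weighted by relative expression level."""
    lengths_nt = np.asarray(lengths_nt, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("at least one transcript must have positive weight")
    return float((lengths_nt * weights).sum() / total)


def estimate_targeted_mass(ercc_mass_fg: float, ercc_read_fraction: float) -> float:
    """Estimate the mass of targeted (endogenous) RNA in picograms.

    The known spiked ERCC mass divided by the average fraction of reads
    assigned to spike-ins gives the total mass; the targeted mass is the
    total minus the spike mass.
    """
    if ercc_mass_fg <= 0:
        raise ValueError("ERCC mass must be positive")
    if not (0 < ercc_read_fraction <= 1):
        raise ValueError("ERCC read fraction must be in (0, 1]")
    total_fg = ercc_mass_fg / ercc_read_fraction
    return (total_fg - ercc_mass_fg) / 1000.0  # fg -> pg


def expected_molecules(bulk: BulkReference, targeted_mass_pg: float) -> MoleculeExpectation:
    """Expected number of molecules per gene in a diluted replicate.

    total = targeted mass / mass of the expression-weighted average
    transcript; M_g = relative frequency x total.
    """
    if targeted_mass_pg <= 0:
        raise ValueError("targeted mass must be positive")
    if bulk.isoforms is not None:
        avg_len = weighted_average_transcript_length(
            bulk.isoforms["length_nt"], bulk.isoforms["weight"]
        )
    else:
        avg_len = weighted_average_transcript_length(
            bulk.effective_length, bulk.relative_frequency
        )
    avg_mass = rna_molecule_mass(avg_len)
    total = targeted_mass_pg / avg_mass
    return MoleculeExpectation(
        targeted_mass_pg=targeted_mass_pg,
        average_transcript_length_nt=avg_len,
        average_transcript_mass_pg=avg_mass,
        total_molecules=total,
        gene_id=bulk.gene_id,
        expected_molecules=bulk.relative_frequency * total,
    )


def ercc_expected_molecules(panel: ErccPanel) -> pd.DataFrame:
    """Expected molecules per spike-in transcript from the known spiked
    mass and molarities."""
    if panel.mass_fg <= 0:
        raise ValueError("panel has no spiked mass")
    avg_len = weighted_average_transcript_length(panel.length_nt, panel.molar_fraction)
    avg_mass = rna_molecule_mass(avg_len)  # pg
    total = (panel.mass_fg / 1000.0) / avg_mass
    return pd.DataFrame(
        {
            "transcript_id": panel.transcript_id,
            "expected_molecules": panel.molar_fraction * total,
        }
    )


def ct_to_log10_molecules(
    ct_values: pd.Series, detection_limit: float = 35.0
) -> pd.Series:
    """Convert qPCR threshold cycles to log10 molecule counts.

    A C_T at the detection limit corresponds to a single molecule, and each
    cycle below it doubles the amount: log2 molecules = limit - C_T.  Genes
    above the limit (undetectable) and genes with multiple reported C_T
    values are removed.
    """
    ct = pd.Series(ct_values, dtype=float)
    dup = ct.index[ct.index.duplicated(keep=False)]
    ct = ct.drop(index=dup)
    ct = ct[ct <= detection_limit]
    return (detection_limit - ct) * np.log10(2.0)
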