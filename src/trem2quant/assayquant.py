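"""Targeted-proteomics quantitation of TREM2 species and small assay ratios.

Parallel-reaction-monitoring (PRM) runs quantify four tryptic peptides, one
per TREM2 species: the soluble ectodomain (sTREM2) and full-length receptor
(flTREM2) of each allele (wild-type and H157Y). Each digest is spiked with a
known femtomole amount of stable isotope-labeled internal standard (SIL-IS)
peptide per species, so the absolute molar amount of the native peptide is

    fmol = (native peak area / SIL-IS peak area) * spike_fmol

The soluble-to-full-length molar ratio (s/fl) indexes receptor shedding and
is computed globally and per allele. The module also carries the study's
small assay normalizations: qPCR relative expression by 2^-dCt, the
C-terminal/N-terminal Trem2 Ct ratio, and fold-of-reference scaling of
ELISA-style measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SPECIES",
    "PeptideMeasurement",
    "TremQuant",
    "prm_amount",
    "trem2_summary",
    "rel_expr_2dct",
    "ct_ratio_cn",
    "fold_of_reference",
    "read_prm_manifest",
    "quantify_manifest",
]

SPECIES = ("sTREM2-WT", "flTREM2-WT", "sTREM2-H157Y", "flTREM2-H157Y")
DEFAULT_SPIKE_FMOL = 5.0


@dataclass(frozen=True)
class PeptideMeasurement:
    """Native and internal-standard chromatographic peak areas for one peptide."""

    species: str
    native_area: float
    sil_area: float
    spike_fmol: float = DEFAULT_SPIKE_FMOL
    sample_id: str = ""
    genotype: str = ""

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown TREM2 species {self.species!r}; expected one of {SPECIES}")
        if self.native_area < 0 or self.sil_area < 0:
            raise ValueError("peak areas must be nonnegative")
        if self.spike_fmol <= 0:
            raise ValueError("spike_fmol must be positive")


@dataclass
class TremQuant:
    """Per-sample TREM2 amounts (fmol) and soluble/full-length ratios."""

    sample_id: str
    amounts_fmol: dict  # species -> fmol
    fl_total_fmol: float
    s_total_fmol: float
    s_fl_ratio: float  # nan when fl total is 0
    s_fl_ratio_WT: float
    s_fl_ratio_H157Y: float
    flags: list


def prm_amount(measurement: PeptideMeasurement) -> float:
    """Absolute molar amount from the native-to-internal-standard area ratio."""
    if measurement.sil_area == 0:
        raise ValueError(
            f"{measurement.species} in sample {measurement.sample_id or '?'}: "
            "internal-standard peak area is zero, peptide is unquantifiable"
        )
    return measurement.native_area / measurement.sil_area * measurement.spike_fmol


def trem2_summary(measurements) -> TremQuant:
    """Summarize one sample's peptide measurements into amounts and ratios.

    Totals sum the species present; the global and allele-specific s/fl
    ratios are NaN (and flagged) wherever the full-length denominator is 0.
    """
    measurements = list(measurements)
    if not measurements:
        raise ValueError("no measurements supplied")
    sample_ids = {m.sample_id for m in measurements}
    if len(sample_ids) > 1:
        raise ValueError(f"measurements span multiple samples: {sorted(sample_ids)}")
    seen = [m.species for m in measurements]
    if len(set(seen)) != len(seen):
        raise ValueError("duplicate species in one sample")
    amounts = {m.species: prm_amount(m) for m in measurements}
    flags: list[str] = []

    def ratio(s_key: str, fl_key: str, label: str) -> float:
        s = amounts.get(s_key, 0.0)
        fl = amounts.get(fl_key, 0.0)
        if fl_key in amounts and fl > 0:
            return s / fl
        flags.append(f"{label}: full-length amount is 0 or absent, ratio undefined")
        return float("nan")

    s_total = sum(v for k, v in amounts.items() if k.startswith("sTREM2"))
    fl_total = sum(v for k, v in amounts.items() if k.startswith("flTREM2"))
    if fl_total > 0:
        global_ratio = s_total / fl_total
    else:
        global_ratio = float("nan")
        flags.append("global: full-length total is 0, ratio undefined")
    return TremQuant(
        sample_id=next(iter(sample_ids)),
        amounts_fmol=amounts,
        fl_total_fmol=float(fl_total),
        s_total_fmol=float(s_total),
        s_fl_ratio=float(global_ratio),
        s_fl_ratio_WT=ratio("sTREM2-WT", "flTREM2-WT", "WT allele"),
        s_fl_ratio_H157Y=ratio("sTREM2-H157Y", "flTREM2-H157Y", "H157Y allele"),
        flags=flags,
    )


def rel_expr_2dct(ct_target, ct_reference):
    """Relative expression by the 2^-dCt method (dCt = Ct_target - Ct_ref)."""
    ct_target = np.asarray(ct_target, dtype=float)
    ct_reference = np.asarray(ct_reference, dtype=float)
    if not (np.all(np.isfinite(ct_target)) and np.all(np.isfinite(ct_reference))):
        raise ValueError("Ct values must be finite")
    out = 2.0 ** (-(ct_target - ct_reference))
    return float(out) if out.ndim == 0 else out


def ct_ratio_cn(ct_cterm, ct_nterm, group_labels, reference_group):
    """Per-sample C-terminal/N-terminal Ct ratio, normalized to a reference group.

    Detects transcripts truncated before the C-terminal amplicon: aberrant
    splicing raises the C-terminal Ct relative to the N-terminal one, so
    affected samples show normalized ratios above 1.
    """
    ct_cterm = np.asarray(ct_cterm, dtype=float)
    ct_nterm = np.asarray(ct_nterm, dtype=float)
    labels = np.asarray(group_labels)
    if not (ct_cterm.shape == ct_nterm.shape == labels.shape):
        raise ValueError("ct_cterm, ct_nterm and group_labels must have equal shapes")
    if np.any(ct_nterm == 0):
        raise ValueError("N-terminal Ct of zero cannot form a ratio")
    ratios = ct_cterm / ct_nterm
    return fold_of_reference(ratios, labels, reference_group)


def fold_of_reference(values, group_labels, reference_group, *, total_protein=None):
    """Divide every value by the mean of the reference group.

    ``total_protein`` optionally divides each value by its sample's total
    protein first (per-sample loading normalization), as done for
    conditioned-medium measurements.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if values.shape != labels.shape:
        raise ValueError("values and group_labels must have equal shapes")
    if total_protein is not None:
        tp = np.asarray(total_protein, dtype=float)
        if np.any(tp <= 0):
            raise ValueError("total protein must be positive")
        values = values / tp
    mask = labels == reference_group
    if not mask.any():
        raise ValueError(f"reference group {reference_group!r} is empty")
    ref_mean = values[mask].mean()
    if ref_mean == 0:
        raise ValueError("reference-group mean is zero; cannot normalize")
    return values / ref_mean


def read_prm_manifest(path) -> list[PeptideMeasurement]:
    """Read a PRM manifest CSV (sample_id, genotype, species, native_area,
    sil_area[, spike_fmol]) into measurements."""
    df = pd.read_csv(path)
    required = {"sample_id", "genotype", "species", "native_area", "sil_area"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"PRM manifest missing columns {sorted(missing)}")
    if "spike_fmol" not in df.columns:
        df = df.assign(spike_fmol=DEFAULT_SPIKE_FMOL)
    return [
        PeptideMeasurement(
            species=row.species,
            native_area=float(row.native_area),
            sil_area=float(row.sil_area),
            spike_fmol=float(row.spike_fmol),
            sample_id=str(row.sample_id),
            genotype=str(row.genotype),
        )
        for row in df.itertuples(index=False)
    ]


def quantify_manifest(measurements, *, reference_group=None) -> pd.DataFrame:
    """Tidy per-sample quantitation table; optional fold-of-reference columns.

    ``reference_group`` (a genotype label) appends columns normalizing the
    soluble and full-length totals to that group's means.
    """
    by_sample: dict[str, list[PeptideMeasurement]] = {}
    genotype: dict[str, str] = {}
    for m in measurements:
        by_sample.setdefault(m.sample_id, []).append(m)
        genotype[m.sample_id] = m.genotype
    rows = []
    for sid in sorted(by_sample):
        q = trem2_summary(by_sample[sid])
        rows.append({
            "sample_id": sid,
            "genotype": genotype[sid],
            **{f"{sp}_fmol": q.amounts_fmol.get(sp, np.nan) for sp in SPECIES},
            "s_total_fmol": q.s_total_fmol,
            "fl_total_fmol": q.fl_total_fmol,
            "s_fl_ratio": q.s_fl_ratio,
            "s_fl_ratio_WT": q.s_fl_ratio_WT,
            "s_fl_ratio_H157Y": q.s_fl_ratio_H157Y,
        })
    df = pd.DataFrame(rows)
    if reference_group is not None and not df.empty:
        for col in ("s_total_fmol", "fl_total_fmol"):
            df[f"{col}_fold_of_{reference_group}"] = fold_of_reference(
                df[col].to_numpy(), df["genotype"].to_numpy(), reference_group
            )
    return df
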