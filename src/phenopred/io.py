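"""File ingestion and serialization: genotypes, phenotypes, spectra, kernels.

All tabular formats are plain CSV (comma, UTF-8, '.' decimal).  Genotypes
additionally read from VCF (dosage from the GT field, requires cyvcf2).
Readers validate rather than coerce: missing factor columns, non-numeric
reflectance, duplicated plot rows, and out-of-order wavelength headers are
errors that name the offending column or rows.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .spectra import SpectraMatrix
from .varcomp import PlotRecordTable

__all__ = [
    "RunConfig",
    "read_genotypes",
    "read_spectra",
    "read_phenotypes",
    "write_genotypes_csv",
    "write_genotypes_vcf",
    "write_spectra_csv",
    "write_kernel_csv",
    "read_kernel_csv",
]

logger = logging.getLogger(__name__)

FACTOR_COLUMNS = ("environment", "replicate", "female", "male", "hybrid")


@dataclass
class RunConfig:
    """Serializable settings for a reproducible pipeline run."""

    genotypes: str | None = None
    phenotypes: str | None = None
    spectra: str | None = None
    output_dir: str = "."
    t: int | None = None
    r: int = 2
    window: int = 11
    polyorder: int = 2
    scale_with_std: bool = True
    n_iter: int = 5000
    burn_in: int = 1000
    thin: int = 10
    cv_repeats: int = 50
    held_out_env: str | None = None
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(
    path: str | Path,
    fmt: str | None = None,
    max_missing: float = 0.05,
) -> pd.DataFrame:
    """Dosage matrix (individuals x markers) from CSV or VCF.

    Markers with more than ``max_missing`` missing genotype calls are
    removed; remaining missing values are imputed to the marker (column)
    mean.  CSV layout: first column individual id, one column per marker.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in (".vcf", ".gz") else "csv"
    if fmt == "csv":
        frame = pd.read_csv(path, index_col=0)
        if frame.index.duplicated().any():
            dups = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated individual ids: {dups}")
        if frame.columns.duplicated().any():
            raise ValueError("duplicated marker ids in header")
        bad = [c for c in frame.columns if not pd.api.types.is_numeric_dtype(frame[c])]
        if bad:
            raise ValueError(f"non-numeric dosage column(s): {bad[:5]}")
        X = frame.astype(float)
    elif fmt == "vcf":
        X = _read_vcf_dosages(path)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")
    frac_missing = X.isna().mean(axis=0)
    drop = frac_missing.index[frac_missing > max_missing]
    if len(drop):
        logger.info("removing %d marker(s) with >%g%% missing", len(drop), 100 * max_missing)
        X = X.drop(columns=drop)
    if X.shape[1] == 0:
        raise ValueError("no markers left after missingness filtering")
    X = X.fillna(X.mean(axis=0))
    return X


def _read_vcf_dosages(path: Path) -> pd.DataFrame:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF requires cyvcf2") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    markers, rows = [], []
    for var in vcf:
        markers.append(var.ID or f"{var.CHROM}:{var.POS}")
        gts = var.genotypes  # [[a1, a2, phased], ...]
        dos = []
        for g in gts:
            alleles = [a for a in g[:-1] if a >= 0]
            dos.append(float(sum(alleles)) if alleles else np.nan)
        rows.append(dos)
    mat = np.array(rows).T  # samples x markers
    return pd.DataFrame(mat, index=samples, columns=markers)


def write_genotypes_csv(dosages: pd.DataFrame, path: str | Path) -> None:
    dosages.to_csv(path, index_label="id")


def write_genotypes_vcf(dosages: pd.DataFrame, path: str | Path) -> None:
    """Minimal single-chromosome VCF with GT calls from 0/1/2 dosages."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##contig=<ID=1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(str(i) for i in dosages.index),
    ]
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1"}
    for j, marker in enumerate(dosages.columns):
        calls = []
        for v in dosages[marker]:
            if pd.isna(v):
                calls.append("./.")
            else:
                calls.append(gt_code.get(int(round(v)), "./."))
        lines.append(
            f"1\t{j + 1}\t{marker}\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(calls)
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# phenotypes


def read_phenotypes(path: str | Path, traits: list[str] | None = None) -> PlotRecordTable:
    """Long-format plot records with validated factor columns."""
    frame = pd.read_csv(path)
    missing = [c for c in FACTOR_COLUMNS if c not in frame.columns]
    if missing:
        raise KeyError(f"phenotype file lacks required column(s): {missing}")
    return PlotRecordTable(frame, traits=traits or [])


def write_phenotypes_csv(records: PlotRecordTable, path: str | Path) -> None:
    records.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# spectra


def read_spectra(path: str | Path) -> SpectraMatrix:
    """Wide CSV: label columns, then one numeric column per band (header nm)."""
    frame = pd.read_csv(path)
    band_cols, labels_cols = [], []
    for c in frame.columns:
        try:
            float(c)
            band_cols.append(c)
        except ValueError:
            labels_cols.append(c)
    if not band_cols:
        raise ValueError("no numeric wavelength columns found in header")
    wl = np.array([float(c) for c in band_cols])
    if np.any(np.diff(wl) <= 0):
        bad = band_cols[int(np.argmax(np.diff(wl) <= 0)) + 1]
        raise ValueError(f"wavelength header out of order at column {bad!r}")
    values = frame[band_cols].to_numpy()
    nonnum = frame[band_cols].map(lambda v: not isinstance(v, (int, float, np.number)))
    if nonnum.to_numpy().any():
        raise ValueError("non-numeric reflectance values present")
    labels = frame[labels_cols] if labels_cols else None
    return SpectraMatrix(values.astype(float), wl, labels)


def write_spectra_csv(spectra: SpectraMatrix, path: str | Path) -> None:
    spectra.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# kernels


def write_kernel_csv(kernel, path: str | Path) -> None:
    kernel.to_frame().to_csv(path, index_label="id")


def read_kernel_csv(path: str | Path, provenance: str = "unknown"):
    from .kernels import RelationshipKernel

    frame = pd.read_csv(path, index_col=0)
    frame.columns = list(frame.columns)
    return RelationshipKernel(frame.to_numpy(dtype=float), list(frame.index), provenance)
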