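"""Synthetic factorial-trial data: genotypes, trait records, NIR spectra.

The generator emulates the statistical structure of a multi-environment
hybrid trial from a complete factorial mating design: inbred parents are
genotyped at biallelic markers, F1 hybrids inherit the parental-mean
dosage, plot-level trait values decompose into female-GCA / male-GCA / SCA
/ environment / G-by-E / replicate / residual variance components, and
per-plot reflectance spectra decompose band-wise into the same kinds of
shares on a smooth spectral basis.

Defaults are the study conditions the analysis assumes: a 10 x 10
factorial (100 hybrids), 8 environments with 2 replicates, trait variance
components on the grain-yield scale, and a 400-2500 nm reflectance grid at
0.5 nm (half-open, 4200 bands).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .design import DesignSpec
from .kernels import sca_kronecker, vanraden_relationship
from .spectra import SpectraMatrix
from .varcomp import PlotRecordTable

__all__ = [
    "TraitGenArchitecture",
    "SpectraGenSpec",
    "GRAIN_YIELD_COMPONENTS",
    "simulate_parent_genotypes",
    "derive_hybrid_genotypes",
    "simulate_trait_records",
    "simulate_spectra_records",
    "trait_from_spectra",
    "FactorialSimulator",
]

# grain-yield-scale variance components (trait units^2) used as the default
# trait architecture: female GCA, male GCA, SCA, environment, the three
# G-by-E interactions, replicate-in-environment, and plot residual
GRAIN_YIELD_COMPONENTS: dict[str, float] = {
    "f": 0.18,
    "m": 0.18,
    "fm": 0.03,
    "s": 1.30,
    "fs": 0.16,
    "ms": 0.09,
    "fms": 0.078,
    "r_s": 0.02,
    "e": 0.634,
}

TERM_FACTORS: dict[str, tuple[str, ...]] = {
    "f": ("female",),
    "m": ("male",),
    "fm": ("female", "male"),
    "s": ("environment",),
    "fs": ("female", "environment"),
    "ms": ("male", "environment"),
    "fms": ("female", "male", "environment"),
    "r_s": ("environment", "replicate"),
}


@dataclass(frozen=True)
class TraitGenArchitecture:
    """Per-trait variance components and the genetic-effect mode.

    ``components`` maps the combined-model term names (f, m, fm, s, fs, ms,
    fms, r_s, e) to non-negative variances in trait units squared.  With
    ``genomic=True`` the genetic terms (f, m, fm and their environment
    interactions) are tied to the simulated genotypes — GCA effects are
    marker-effect sums, SCA effects are drawn from the Kronecker SCA
    kernel — so genomic prediction has signal to recover.  With
    ``genomic=False`` every term is drawn i.i.d. normal.
    """

    components: dict[str, float] = field(
        default_factory=lambda: dict(GRAIN_YIELD_COMPONENTS)
    )
    mu: float = 6.44
    genomic: bool = True

    def __post_init__(self) -> None:
        unknown = set(self.components) - set(TERM_FACTORS) - {"e"}
        if unknown:
            raise KeyError(f"unknown variance-component names: {sorted(unknown)}")
        for k, v in self.components.items():
            if v < 0:
                raise ValueError(f"variance component {k} is negative: {v}")

    def with_components(self, **overrides: float) -> "TraitGenArchitecture":
        comp = dict(self.components)
        comp.update(overrides)
        return replace(self, components=comp)


@dataclass(frozen=True)
class SpectraGenSpec:
    """Reflectance-spectra generator settings.

    ``shares`` are per-band variance fractions for the female, male, hybrid
    (SCA-like), environment, G-by-E, replicate, and residual components;
    they must be non-negative and sum to 1.  Effects for all but the
    residual are drawn on a smooth cubic B-spline basis with ``n_knots``
    interior knots, mimicking smooth NIR curves; the residual is white
    noise.  The default shares reproduce band-wise broad-sense heritability
    around 0.97 under the default 8-environment, 2-replicate design.
    """

    start_nm: float = 400.0
    stop_nm: float = 2500.0
    step_nm: float = 0.5
    shares: dict[str, float] = field(
        default_factory=lambda: {
            "female": 0.176,
            "male": 0.263,
            "hybrid": 0.051,
            "environment": 0.341,
            "gxe": 0.10,
            "replicate": 0.019,
            "residual": 0.050,
        }
    )
    n_knots: int = 40
    total_variance: float = 1.0

    SHARE_KEYS = (
        "female",
        "male",
        "hybrid",
        "environment",
        "gxe",
        "replicate",
        "residual",
    )

    def __post_init__(self) -> None:
        unknown = set(self.shares) - set(self.SHARE_KEYS)
        if unknown:
            raise KeyError(f"unknown share names: {sorted(unknown)}")
        vals = [self.shares.get(k, 0.0) for k in self.SHARE_KEYS]
        if any(v < 0 for v in vals):
            raise ValueError("variance shares must be non-negative")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError(f"variance shares must sum to 1, got {sum(vals)}")
        if self.n_bands < 1:
            raise ValueError("grid yields no bands")

    @property
    def wavelengths(self) -> np.ndarray:
        # half-open grid [start, stop): 400-2500 at 0.5 nm -> 4200 bands
        return np.arange(self.start_nm, self.stop_nm - 1e-9, self.step_nm)

    @property
    def n_bands(self) -> int:
        return len(self.wavelengths)


# ---------------------------------------------------------------------------
# genotypes


def simulate_parent_genotypes(
    n_parents: int,
    n_markers: int,
    maf_range: tuple[float, float] = (0.1, 0.5),
    inbred: bool = True,
    seed: int | None = None,
    prefix: str = "P",
) -> pd.DataFrame:
    """Biallelic dosage matrix (parents x markers) with codes 0/1/2.

    Marker allele frequencies are drawn uniformly from ``maf_range``.
    Inbred parents are fully homozygous (dosages in {0, 2}, allele drawn
    Bernoulli(p)); outbred parents get Binomial(2, p) dosages.
    """
    if n_parents < 2 or n_markers < 1:
        raise ValueError("need n_parents >= 2 and n_markers >= 1")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be a non-empty interval within (0, 0.5]")
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=n_markers)
    if inbred:
        dosages = 2 * (rng.random((n_parents, n_markers)) < p).astype(np.int8)
    else:
        dosages = rng.binomial(2, p, size=(n_parents, n_markers)).astype(np.int8)
    ids = [f"{prefix}{i + 1:02d}" for i in range(n_parents)]
    cols = [f"SNP{j + 1}" for j in range(n_markers)]
    return pd.DataFrame(dosages, index=ids, columns=cols)


def derive_hybrid_genotypes(
    female_dosages: pd.DataFrame,
    male_dosages: pd.DataFrame,
    design: DesignSpec,
) -> pd.DataFrame:
    """Expected F1 dosages: the parental mean per marker.

    For inbred (homozygous) parents this is the deterministic F1 genotype:
    opposite homozygotes give a heterozygous (dosage 1) hybrid.
    """
    if list(female_dosages.columns) != list(male_dosages.columns):
        raise ValueError("female and male parents must share the marker set and order")
    hyb = design.hybrid_table()
    F = female_dosages.to_numpy(dtype=float)
    M = male_dosages.to_numpy(dtype=float)
    fpos = {p: i for i, p in enumerate(female_dosages.index)}
    mpos = {p: i for i, p in enumerate(male_dosages.index)}
    out = np.stack(
        [
            (F[fpos[f]] + M[mpos[m]]) / 2.0
            for f, m in zip(hyb["female"], hyb["male"])
        ]
    )
    return pd.DataFrame(out, index=hyb["hybrid"].tolist(), columns=female_dosages.columns)


# ---------------------------------------------------------------------------
# trait records


def _mvn_from_kernel(K: np.ndarray, sigma2: float, rng: np.random.Generator) -> np.ndarray:
    """Draw kernel-correlated effects whose expected sample variance is sigma2.

    The scaling targets the across-level (ddof=1) variance because that is
    the quantity a variance-component fit measures: for u ~ N(0, cK) the
    expected sample variance is c (tr K - 1'K1/q) / (q - 1).
    """
    if sigma2 == 0.0:
        return np.zeros(K.shape[0])
    w, V = np.linalg.eigh(K)
    w = np.clip(w, 0.0, None)
    support = w > w[-1] * 1e-10 if w[-1] > 0 else w > 0
    if not support.any():
        return np.zeros(K.shape[0])
    # average variance per supported direction = sigma2; relationship
    # matrices on centered dosages are sum-to-zero, so the support spans
    # exactly the contrast space the variance component refers to
    c = sigma2 * support.sum() / float(w[support].sum())
    z = rng.standard_normal(len(w))
    return (V * np.sqrt(c * w)) @ z


def _marker_effect_draw(
    X: np.ndarray, sigma2: float, rng: np.random.Generator
) -> np.ndarray:
    """Genetic values as marker-effect sums with expected sample variance sigma2.

    Columns are centered, so the values sum to zero across parents; the
    effect scale targets the ddof=1 sample variance for the same reason as
    :func:`_mvn_from_kernel`.
    """
    if sigma2 == 0.0:
        return np.zeros(X.shape[0])
    Xc = X - X.mean(axis=0)
    total = float((Xc**2).sum())
    if total == 0:
        return np.zeros(X.shape[0])
    alpha = rng.standard_normal(X.shape[1]) * np.sqrt(
        sigma2 * (X.shape[0] - 1) / total
    )
    return Xc @ alpha


def simulate_trait_records(
    design: DesignSpec,
    arch: TraitGenArchitecture,
    seed: int | None = None,
    female_dosages: pd.DataFrame | None = None,
    male_dosages: pd.DataFrame | None = None,
    trait: str = "trait",
) -> PlotRecordTable:
    """Plot records y = mu + f + m + fm + s + fs + ms + fms + r(s) + e.

    Each term is drawn independently, zero-mean, at its configured
    variance.  In genomic mode (the default when parent dosages are
    supplied and ``arch.genomic``) the GCA terms are marker-effect sums and
    the SCA term is drawn from the Kronecker SCA kernel; G-by-E terms are
    drawn per environment from the matching parent kernel so interaction
    kernels carry signal.
    """
    frame = design.plot_frame()
    rng = np.random.default_rng(seed)
    comp = {k: arch.components.get(k, 0.0) for k in (*TERM_FACTORS, "e")}
    y = np.full(len(frame), arch.mu, dtype=float)

    genomic = (
        arch.genomic and female_dosages is not None and male_dosages is not None
    )
    effects: dict[str, np.ndarray] = {}
    envs = list(design.environments)
    if genomic:
        Gf = vanraden_relationship(female_dosages, provenance="genomic-female")
        Gm = vanraden_relationship(male_dosages, provenance="genomic-male")
        H = sca_kronecker(Gf, Gm, design.hybrid_table())
        f_eff = _marker_effect_draw(
            female_dosages.to_numpy(dtype=float), comp["f"], rng
        )
        m_eff = _marker_effect_draw(male_dosages.to_numpy(dtype=float), comp["m"], rng)
        fm_eff = _mvn_from_kernel(H.matrix, comp["fm"], rng)
        effects["f"] = dict(zip(female_dosages.index, f_eff))
        effects["m"] = dict(zip(male_dosages.index, m_eff))
        effects["fm"] = dict(zip(H.ids, fm_eff))
        # per-environment kernel draws for the interaction terms
        fs = {
            (fid, env): v
            for env in envs
            for fid, v in zip(
                Gf.ids, _mvn_from_kernel(Gf.matrix, comp["fs"], rng)
            )
        }
        ms = {
            (mid, env): v
            for env in envs
            for mid, v in zip(
                Gm.ids, _mvn_from_kernel(Gm.matrix, comp["ms"], rng)
            )
        }
        fms = {
            (hid, env): v
            for env in envs
            for hid, v in zip(H.ids, _mvn_from_kernel(H.matrix, comp["fms"], rng))
        }
        y += frame["female"].map(effects["f"]).to_numpy()
        y += frame["male"].map(effects["m"]).to_numpy()
        y += frame["hybrid"].map(effects["fm"]).to_numpy()
        keys_f = list(zip(frame["female"], frame["environment"]))
        keys_m = list(zip(frame["male"], frame["environment"]))
        keys_h = list(zip(frame["hybrid"], frame["environment"]))
        y += np.array([fs[k] for k in keys_f])
        y += np.array([ms[k] for k in keys_m])
        y += np.array([fms[k] for k in keys_h])
        iid_terms = ("s", "r_s")
    else:
        iid_terms = tuple(TERM_FACTORS)

    for term in iid_terms:
        cols = list(TERM_FACTORS[term])
        codes, _ = pd.factorize(frame[cols].apply(tuple, axis=1))
        draw = rng.normal(0.0, np.sqrt(comp[term]), codes.max() + 1)
        y += draw[codes]
    y += rng.normal(0.0, np.sqrt(comp["e"]), len(frame))
    frame[trait] = y
    return PlotRecordTable(frame, traits=[trait])


# ---------------------------------------------------------------------------
# spectra


def _smooth_basis(n_bands: int, n_knots: int, degree: int = 3) -> np.ndarray:
    """Row-normalized cubic B-spline basis: unit per-band draw variance."""
    x = np.linspace(0.0, 1.0, n_bands)
    knots = np.concatenate(
        [
            np.zeros(degree),
            np.linspace(0.0, 1.0, n_knots - degree + 1),
            np.ones(degree),
        ]
    )
    B = BSpline.design_matrix(x, knots, degree).toarray()
    norms = np.sqrt((B**2).sum(axis=1, keepdims=True))
    return B / norms


def simulate_spectra_records(
    design: DesignSpec,
    spec: SpectraGenSpec | None = None,
    seed: int | None = None,
) -> SpectraMatrix:
    """Per-plot reflectance spectra with configured band-wise variance shares.

    Each band value is a smooth baseline plus additive female / male /
    hybrid / environment / G-by-E / replicate curves (drawn on a smooth
    B-spline basis, each scaled to its variance share) plus white residual
    noise.  Setting the replicate and residual shares to zero makes
    replicate spectra of a hybrid within an environment identical.
    """
    if spec is None:
        spec = SpectraGenSpec()
    rng = np.random.default_rng(seed)
    frame = design.plot_frame()
    n_rec = len(frame)
    n_bands = spec.n_bands
    B = _smooth_basis(n_bands, spec.n_knots)
    k = B.shape[1]
    sd_total = np.sqrt(spec.total_variance)

    def level_curves(levels: list) -> dict:
        return {
            lev: B @ rng.standard_normal(k) for lev in levels
        }

    factor_levels = {
        "female": sorted(frame["female"].unique()),
        "male": sorted(frame["male"].unique()),
        "hybrid": sorted(frame["hybrid"].unique()),
        "environment": sorted(frame["environment"].unique()),
    }
    gxe_levels = sorted(set(zip(frame["hybrid"], frame["environment"])))
    rep_levels = sorted(set(zip(frame["environment"], frame["replicate"])))

    values = np.zeros((n_rec, n_bands))
    # smooth baseline common to every record (does not enter variance shares)
    baseline = 0.5 + 0.1 * (B @ rng.standard_normal(k))
    values += baseline

    assignments = {
        "female": frame["female"],
        "male": frame["male"],
        "hybrid": frame["hybrid"],
        "environment": frame["environment"],
        "gxe": pd.Series(list(zip(frame["hybrid"], frame["environment"]))),
        "replicate": pd.Series(list(zip(frame["environment"], frame["replicate"]))),
    }
    levels_of = {
        **factor_levels,
        "gxe": gxe_levels,
        "replicate": rep_levels,
    }
    for name in ("female", "male", "hybrid", "environment", "gxe", "replicate"):
        share = spec.shares.get(name, 0.0)
        if share == 0.0:
            continue
        curves = level_curves(levels_of[name])
        sd = np.sqrt(share) * sd_total
        stacked = np.stack([curves[lev] for lev in assignments[name]])
        values += sd * stacked
    resid_share = spec.shares.get("residual", 0.0)
    if resid_share > 0:
        values += np.sqrt(resid_share) * sd_total * rng.standard_normal(
            (n_rec, n_bands)
        )
    labels = frame[["environment", "replicate", "female", "male", "hybrid"]].copy()
    labels["record"] = (
        labels["environment"] + ":" + labels["replicate"] + ":" + labels["hybrid"]
    )
    return SpectraMatrix(values, spec.wavelengths, labels)


def trait_from_spectra(
    spectra: SpectraMatrix,
    band_window: tuple[int, int] = (50, 100),
    signal_variance: float = 1.0,
    residual_variance: float = 0.25,
    mu: float = 0.0,
    seed: int | None = None,
    trait: str = "trait",
) -> PlotRecordTable:
    """Plot records whose signal is a functional of the record's spectrum.

    The trait value is the record's mean reflectance over ``band_window``
    (standardized, then scaled to ``signal_variance``) plus white noise.
    Because the signal lives entirely in the spectra — including their
    environment and G-by-E components — phenomic prediction sees it
    directly while marker-based prediction has no channel to it.
    """
    if spectra.labels is None:
        raise ValueError("spectra must carry record labels")
    lo, hi = band_window
    if not (0 <= lo < hi <= spectra.n_bands):
        raise ValueError("band window out of range")
    score = spectra.values[:, lo:hi].mean(axis=1)
    sd = score.std(ddof=1)
    if sd == 0:
        raise ValueError("spectral score is constant over the window")
    score = (score - score.mean()) / sd * np.sqrt(signal_variance)
    rng = np.random.default_rng(seed)
    y = mu + score + rng.normal(0.0, np.sqrt(residual_variance), len(score))
    frame = spectra.labels.drop(columns="record").copy()
    frame[trait] = y
    return PlotRecordTable(frame, traits=[trait])


# ---------------------------------------------------------------------------
# one-stop simulator


@dataclass
class FactorialSimulator:
    """Generate a coherent synthetic dataset for the whole pipeline.

    Desk-scale defaults: a 10 x 10 factorial, 8 environments x 2
    replicates, 2000 markers, grain-yield-scale trait components, and the
    default spectra shares.  ``simulate`` returns genotypes, plot records,
    and spectra drawn from one seed.
    """

    design: DesignSpec = field(
        default_factory=lambda: DesignSpec(10, 10, {f"E{i + 1}": 2 for i in range(8)})
    )
    n_markers: int = 2000
    maf_range: tuple[float, float] = (0.1, 0.5)
    arch: TraitGenArchitecture = field(default_factory=TraitGenArchitecture)
    spectra_spec: SpectraGenSpec = field(default_factory=SpectraGenSpec)

    def simulate(self, seed: int = 0) -> dict:
        ss = np.random.SeedSequence(seed)
        s_geno, s_trait, s_spec = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
        females = simulate_parent_genotypes(
            self.design.n_female, self.n_markers, self.maf_range, True, s_geno, "F"
        )
        males = simulate_parent_genotypes(
            self.design.n_male, self.n_markers, self.maf_range, True, s_geno + 1, "M"
        )
        hybrids = derive_hybrid_genotypes(females, males, self.design)
        records = simulate_trait_records(
            self.design, self.arch, s_trait, females, males
        )
        spectra = simulate_spectra_records(self.design, self.spectra_spec, s_spec)
        return {
            "female_dosages": females,
            "male_dosages": males,
            "hybrid_dosages": hybrids,
            "records": records,
            "spectra": spectra,
        }
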