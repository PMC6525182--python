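"""Synthetic global root-trait dataset generator.

Emulates the statistical structure of a global absorptive-root trait
compilation — 505 woody and 361 non-woody species with lognormal diameter
distributions, a linear tToS-diameter allometry with Gaussian noise, stele
radii either as the exact geometric complement of tToS or from an
independent regression, two-tissue mixture RTD and RN, Brownian-motion
trait evolution (with a lambda transform) on a pure-birth phylogeny, and
the grouping factors the comparative analyses need (growth form,
mycorrhizal type, root-order sampling class, climatic zone, data-source
class).

Every record's generating truth is written to a provenance sidecar so that
each fitted quantity downstream can be checked against the value that
produced it.  All randomness flows from one master seed through named
substreams, so the same config always yields byte-identical tables.

Noise defaults
--------------
tToS noise is 0.02 mm for woody roots and 0.006 mm for non-woody roots;
independent-mode stele-radius noise is 0.01 mm.  The asymmetry is
deliberate: non-woody absorptive roots are thin (median diameter
0.25 mm, tToS around 0.09 mm), and a 0.02 mm measurement sd there would
exceed 20% relative error and push >1% of stele radii negative, which the
generator treats as a configuration error (see ``out_of_domain_policy``).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .allometry import AllometryParams, TissueMixture
from .phylo import simulate_tree, simulate_bm_trait, tip_labels

__all__ = [
    "GroupConfig",
    "GeneratorConfig",
    "woody_defaults",
    "nonwoody_defaults",
    "generate_dataset",
    "make_data_source_classes",
    "inject_outliers",
    "aggregate_species_means",
    "CLIMATIC_ZONES",
    "TRAIT_COLUMNS",
]

CLIMATIC_ZONES = ["tropical", "subtropical", "temperate", "boreal", "Mediterranean"]

TRAIT_COLUMNS = [
    "species",
    "diameter",
    "tToS",
    "SR",
    "PRS",
    "prs_in_domain",
    "RTD",
    "RN",
    "SRL",
    "growth_form",
    "mycorrhiza",
    "root_sampling",
    "data_source_class",
    "climatic_zone",
    "study",
]


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named child stream of the master seed (stable across runs)."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


def _substream_int(seed: int, name: str) -> int:
    return int(_substream(seed, name).integers(0, 2**31 - 1))


@dataclass
class GroupConfig:
    """Generation parameters for one growth form."""

    n: int
    k: float  # tToS-diameter slope
    c: float  # tToS-diameter intercept, mm
    sigma_t: float  # tToS Gaussian noise sd, mm
    sr_mode: str  # "complement" (SR = x/2 - tToS) or "independent"
    k_sr: float | None  # independent-mode SR slope
    c_sr: float | None  # independent-mode SR intercept, mm
    sigma_s: float  # independent-mode SR noise sd, mm
    diam_log_median: float  # log of the median diameter, mm
    diam_log_sd: float
    diam_min: float
    diam_max: float
    mycorrhiza_counts: dict[str, int] = field(default_factory=dict)
    anatomy_n: int | None = None  # species carrying anatomy columns; None = all

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("group size must be >= 0")
        if self.sr_mode not in ("complement", "independent"):
            raise ValueError(f"unknown sr_mode {self.sr_mode!r}")
        if self.sr_mode == "independent" and (self.k_sr is None or self.c_sr is None):
            raise ValueError("independent sr_mode requires k_sr and c_sr")
        AllometryParams(k=self.k, c=self.c)  # raises if k outside (0, 0.5)
        if not 0 < self.diam_min < self.diam_max:
            raise ValueError("need 0 < diam_min < diam_max")


def woody_defaults() -> GroupConfig:
    """Woody group: slope/intercept 0.43 / -0.016 mm, independent SR line
    with slope 0.068 (the printed SR regression is not the exact geometric
    complement of the tToS line, so independent noise reproduces that)."""
    return GroupConfig(
        n=505,
        k=0.43,
        c=-0.016,
        sigma_t=0.02,
        sr_mode="independent",
        k_sr=0.068,
        c_sr=0.016,
        sigma_s=0.01,
        diam_log_median=float(np.log(0.35)),
        diam_log_sd=0.4,
        diam_min=0.1,
        diam_max=1.2,
        mycorrhiza_counts={
            "AM": 376, "EM": 89, "ERM": 13, "NM": 3, "AM+EM": 17, "unknown": 7,
        },
        anatomy_n=158,
    )


def nonwoody_defaults() -> GroupConfig:
    """Non-woody group: slope/intercept 0.32 / 0.011 mm, SR as the exact
    geometric complement (0.32 + 0.18 = 0.5)."""
    return GroupConfig(
        n=361,
        k=0.32,
        c=0.011,
        sigma_t=0.006,
        sr_mode="complement",
        k_sr=None,
        c_sr=None,
        sigma_s=0.01,
        diam_log_median=float(np.log(0.25)),
        diam_log_sd=0.35,
        diam_min=0.1,
        diam_max=2.0,
        mycorrhiza_counts={"AM": 352, "NM": 6, "unknown": 3},
        anatomy_n=13,
    )


@dataclass
class GeneratorConfig:
    """Full generator configuration.  ``seed`` is mandatory."""

    seed: int
    woody: GroupConfig = field(default_factory=woody_defaults)
    nonwoody: GroupConfig = field(default_factory=nonwoody_defaults)
    mixture: TissueMixture = field(default_factory=TissueMixture)
    sigma_rtd: float = 0.05  # g cm^-3
    sigma_rn: float = 2.0  # mg g^-1
    bm_sigma2: float = 1.0
    bm_lambda: float = 0.8
    n_studies: int = 30
    p_multi_study: float = 0.0  # fraction of species reported by 2 studies
    high_rtd_fraction_correlated: float = 0.53
    high_rtd_fraction_uncorrelated: float = 0.17
    out_of_domain_policy: str = "error"  # or "flag"
    max_out_of_domain: float = 0.01

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.woody.validate()
        self.nonwoody.validate()
        if self.woody.n + self.nonwoody.n < 2:
            raise ValueError("need at least 2 species in total")
        if not 0.0 <= self.bm_lambda <= 1.0:
            raise ValueError("bm_lambda must lie in [0, 1]")
        if self.out_of_domain_policy not in ("error", "flag"):
            raise ValueError("out_of_domain_policy must be 'error' or 'flag'")
        for frac in (
            self.high_rtd_fraction_correlated,
            self.high_rtd_fraction_uncorrelated,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("high-RTD fractions must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def _scaled_counts(counts: dict[str, int], n: int) -> dict[str, int]:
    """Rescale category counts to sum to n (largest-remainder rounding)."""
    total = sum(counts.values())
    if total == n:
        return dict(counts)
    keys = sorted(counts)
    raw = {k: counts[k] * n / total for k in keys}
    out = {k: int(np.floor(raw[k])) for k in keys}
    short = n - sum(out.values())
    for k in sorted(keys, key=lambda k: raw[k] - out[k], reverse=True)[:short]:
        out[k] += 1
    return out


def _categorical_column(
    counts: dict[str, int], n: int, rng: np.random.Generator
) -> np.ndarray:
    scaled = _scaled_counts(counts, n)
    values = np.concatenate([[k] * v for k, v in sorted(scaled.items())])
    return rng.permutation(values)


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, "dendropy.Tree", dict]:  # noqa: F821
    """Simulate the trait table, its phylogeny, and the truth sidecar.

    Pipeline: Yule tree over all species -> lambda-transformed Brownian
    log-diameter mapped into each growth form's lognormal range -> tToS
    from the group's allometry line plus noise -> SR by complement or
    independent regression -> PRS from anatomy (out-of-domain flagged,
    never clipped) -> RTD/RN from the two-tissue mixture plus noise ->
    SRL from the cylinder identity -> grouping factors.
    """
    config.validate()
    seed = config.seed
    n_total = config.woody.n + config.nonwoody.n
    tree = simulate_tree(n_total, seed=_substream_int(seed, "tree"))
    species = np.array(tip_labels(tree))

    # growth forms: a seeded permutation of tips
    rng_form = _substream(seed, "growth_form")
    order = rng_form.permutation(n_total)
    form = np.empty(n_total, dtype=object)
    form[order[: config.woody.n]] = "woody"
    form[order[config.woody.n :]] = "non-woody"

    # phylogenetically structured log-diameter
    z = simulate_bm_trait(
        tree,
        sigma2=config.bm_sigma2,
        root_value=0.0,
        lam=config.bm_lambda,
        seed=_substream_int(seed, "bm_diameter"),
    ).reindex(species).to_numpy()

    df = pd.DataFrame({"species": species, "growth_form": form})
    diameter = np.empty(n_total)
    ttos = np.empty(n_total)
    sr = np.empty(n_total)
    group_cfgs = {"woody": config.woody, "non-woody": config.nonwoody}
    for name, gcfg in group_cfgs.items():
        mask = form == name
        if not mask.any():
            continue
        zg = z[mask]
        z_std = (zg - zg.mean()) / zg.std() if zg.std() > 0 else zg * 0.0
        x = np.exp(gcfg.diam_log_median + gcfg.diam_log_sd * z_std)
        x = np.clip(x, gcfg.diam_min, gcfg.diam_max)
        rng_t = _substream(seed, f"ttos_{name}")
        t = gcfg.k * x + gcfg.c + rng_t.normal(0.0, gcfg.sigma_t, mask.sum())
        if gcfg.sr_mode == "complement":
            s = x / 2.0 - t
        else:
            rng_s = _substream(seed, f"sr_{name}")
            s = gcfg.k_sr * x + gcfg.c_sr + rng_s.normal(
                0.0, gcfg.sigma_s, mask.sum()
            )
        diameter[mask], ttos[mask], sr[mask] = x, t, s

    inner = 2.0 * sr / diameter
    in_domain = (inner >= 0.0) & (inner <= 1.0)
    prs = np.where(in_domain, inner**2, np.nan)
    frac_out = float((~in_domain).mean())
    if frac_out > config.max_out_of_domain and config.out_of_domain_policy == "error":
        raise ValueError(
            f"{frac_out:.1%} of records have out-of-domain PRS "
            f"(> {config.max_out_of_domain:.0%}); reduce the anatomy noise "
            f"sds or raise the minimum diameter, or set "
            f"out_of_domain_policy='flag' if the PRS stage is not needed"
        )

    rng_rtd = _substream(seed, "rtd")
    rng_rn = _substream(seed, "rn")
    rtd = np.full(n_total, np.nan)
    rn = np.full(n_total, np.nan)
    rtd[in_domain] = config.mixture.rtd(prs[in_domain]) + rng_rtd.normal(
        0.0, config.sigma_rtd, int(in_domain.sum())
    )
    rn[in_domain] = config.mixture.rn(prs[in_domain]) + rng_rn.normal(
        0.0, config.sigma_rn, int(in_domain.sum())
    )
    rtd = np.where(np.isnan(rtd), np.nan, np.maximum(rtd, 0.01))
    rn = np.where(np.isnan(rn), np.nan, np.maximum(rn, 0.1))
    with np.errstate(invalid="ignore"):
        srl_vals = 4.0 / (np.pi * rtd * (diameter / 10.0) ** 2) / 100.0

    df["diameter"] = diameter
    df["tToS"] = ttos
    df["SR"] = sr
    df["PRS"] = prs
    df["prs_in_domain"] = in_domain
    df["RTD"] = rtd
    df["RN"] = rn
    df["SRL"] = srl_vals

    # mycorrhizal types, root sampling, climatic zone, study
    myco = np.empty(n_total, dtype=object)
    sampling = np.empty(n_total, dtype=object)
    for name, gcfg in group_cfgs.items():
        mask = form == name
        if not mask.any():
            continue
        rng_m = _substream(seed, f"mycorrhiza_{name}")
        myco[mask] = _categorical_column(gcfg.mycorrhiza_counts, int(mask.sum()), rng_m)
        if name == "woody":
            rng_o = _substream(seed, "root_sampling")
            sampling[mask] = rng_o.choice(
                ["first_order", "up_to_third"], size=int(mask.sum())
            )
        else:
            # non-woody studies sample fine roots by diameter, pooled orders
            sampling[mask] = "up_to_third"
    df["mycorrhiza"] = myco
    df["root_sampling"] = sampling
    rng_z = _substream(seed, "climate")
    df["climatic_zone"] = rng_z.choice(CLIMATIC_ZONES, size=n_total)
    rng_study = _substream(seed, "study")
    df["study"] = [
        f"study{j:03d}" for j in rng_study.integers(1, config.n_studies + 1, n_total)
    ]

    # anatomy availability: only a subset of species carries anatomy columns
    for name, gcfg in group_cfgs.items():
        mask = form == name
        if gcfg.anatomy_n is None or not mask.any():
            continue
        idx = np.flatnonzero(mask)
        rng_a = _substream(seed, f"anatomy_{name}")
        keep = set(rng_a.choice(idx, size=min(gcfg.anatomy_n, idx.size), replace=False))
        drop = [i for i in idx if i not in keep]
        df.loc[drop, ["tToS", "SR", "PRS"]] = np.nan
        df.loc[drop, "prs_in_domain"] = False

    # optional multi-study duplication (off by default)
    if config.p_multi_study > 0:
        rng_dup = _substream(seed, "multi_study")
        dup_mask = rng_dup.random(n_total) < config.p_multi_study
        dups = df.loc[dup_mask].copy()
        dups["study"] = [
            f"study{j:03d}"
            for j in rng_dup.integers(1, config.n_studies + 1, len(dups))
        ]
        numeric = ["diameter", "tToS", "SR", "RTD", "RN"]
        jitter = rng_dup.normal(1.0, 0.02, (len(dups), len(numeric)))
        dups[numeric] = dups[numeric].to_numpy() * jitter
        df = pd.concat([df, dups], ignore_index=True)

    df = make_data_source_classes(
        df,
        config.high_rtd_fraction_correlated,
        config.high_rtd_fraction_uncorrelated,
        seed=_substream_int(seed, "data_source"),
    )
    df = df[TRAIT_COLUMNS]

    truth = {
        "config": config.to_dict(),
        "n_species": n_total,
        "out_of_domain_fraction": frac_out,
        "groups": {
            name: {
                "k": gcfg.k,
                "c": gcfg.c,
                "sr_mode": gcfg.sr_mode,
                "k_sr": gcfg.k_sr if gcfg.sr_mode == "independent" else 0.5 - gcfg.k,
                "c_sr": gcfg.c_sr if gcfg.sr_mode == "independent" else -gcfg.c,
                "sigma_t": gcfg.sigma_t,
                "n": gcfg.n,
            }
            for name, gcfg in group_cfgs.items()
        },
        "mixture": asdict(config.mixture),
        "bm_lambda": config.bm_lambda,
        "bm_sigma2": config.bm_sigma2,
    }
    return df, tree, truth


def make_data_source_classes(
    table: pd.DataFrame,
    high_rtd_fraction_correlated: float = 0.53,
    high_rtd_fraction_uncorrelated: float = 0.17,
    seed: int | None = None,
    rtd_threshold: float | None = None,
    diameter_threshold: float | None = None,
) -> pd.DataFrame:
    """Assign a data-source class by biased sampling of thin high-RTD species.

    Studies reporting "correlated" trait relationships over-sample thin,
    high-RTD roots — the steep end of the nonlinear curve — while studies
    reporting "uncorrelated" traits sample mostly the flat (thick,
    low-RTD) end.  A record counts as thin/high-RTD when its RTD exceeds
    ``rtd_threshold`` (default: the table's mean RTD, the rule separating
    low- from high-RTD roots) *and* its diameter is below
    ``diameter_threshold`` (default: the median diameter).  The class
    sizes are solved so the thin/high-RTD frequency inside each class hits
    the requested fractions exactly (defaults 53% vs 17%); the split is
    infeasible — and raises — when the table's overall frequency lies
    outside the two fractions.
    """
    if len(table) == 0:
        raise ValueError("empty table")
    for frac in (high_rtd_fraction_correlated, high_rtd_fraction_uncorrelated):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    out = table.copy()
    rtd = out["RTD"].to_numpy(dtype=float)
    diam = out["diameter"].to_numpy(dtype=float)
    known = np.isfinite(rtd) & np.isfinite(diam)
    threshold = float(np.nanmean(rtd)) if rtd_threshold is None else rtd_threshold
    d_threshold = (
        float(np.nanmedian(diam)) if diameter_threshold is None else diameter_threshold
    )
    high = known & (rtd > threshold) & (diam < d_threshold)
    n = len(out)
    n_high = int(high.sum())
    f_c, f_u = high_rtd_fraction_correlated, high_rtd_fraction_uncorrelated
    rng = np.random.default_rng(seed)
    labels = np.empty(n, dtype=object)
    if f_c == f_u:
        # no bias requested: a plain random half/half split
        half = n // 2
        perm = rng.permutation(n)
        labels[perm[:half]] = "correlated"
        labels[perm[half:]] = "uncorrelated"
        out["data_source_class"] = labels
        return out
    n_cor = (n_high - f_u * n) / (f_c - f_u)
    if not 0 < n_cor < n:
        raise ValueError(
            f"infeasible fractions: overall high-RTD frequency "
            f"{n_high / n:.2f} is outside [{min(f_c, f_u)}, {max(f_c, f_u)}]"
        )
    n_cor = int(round(n_cor))
    h_c = int(round(f_c * n_cor))
    h_c = min(max(h_c, n_high - (n - n_cor)), n_high)
    high_idx = rng.permutation(np.flatnonzero(high))
    low_idx = rng.permutation(np.flatnonzero(~high))
    cor_rows = np.concatenate([high_idx[:h_c], low_idx[: n_cor - h_c]])
    labels[:] = "uncorrelated"
    labels[cor_rows] = "correlated"
    out["data_source_class"] = labels
    return out


def inject_outliers(
    table: pd.DataFrame,
    n_rn: int = 1,
    n_prs: int = 1,
    magnitude: float = 4.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Inflate RN (and PRS, capped at 1) for randomly chosen records.

    Emulates the occasional wild record a literature compilation carries:
    one exceptionally high RN, one exceptionally high PRS.  Injected rows
    are marked in the hidden truth column ``is_outlier_truth`` so the
    downstream exclusion rule can be scored against them.
    """
    if n_rn + n_prs > len(table):
        raise ValueError("more outliers requested than rows available")
    out = table.copy()
    out["is_outlier_truth"] = False
    rng = np.random.default_rng(seed)
    rn_pool = np.flatnonzero(out["RN"].notna().to_numpy())
    prs_pool = np.flatnonzero(out["PRS"].notna().to_numpy())
    rn_rows = rng.choice(rn_pool, size=min(n_rn, rn_pool.size), replace=False)
    remaining = np.setdiff1d(prs_pool, rn_rows)
    prs_rows = rng.choice(remaining, size=min(n_prs, remaining.size), replace=False)
    col_rn = out.columns.get_loc("RN")
    col_prs = out.columns.get_loc("PRS")
    col_flag = out.columns.get_loc("is_outlier_truth")
    for i in rn_rows:
        out.iat[i, col_rn] = out.iat[i, col_rn] * magnitude
        out.iat[i, col_flag] = True
    for i in prs_rows:
        out.iat[i, col_prs] = min(out.iat[i, col_prs] * magnitude, 1.0)
        out.iat[i, col_flag] = True
    return out


def aggregate_species_means(table: pd.DataFrame) -> pd.DataFrame:
    """One row per species: numeric columns averaged across studies.

    When a species is reported by several studies, its trait value is the
    mean across those studies; categorical columns keep the first value
    (they are constant within species by construction).
    """
    numeric = table.select_dtypes(include=[np.number]).columns.tolist()
    other = [c for c in table.columns if c not in numeric and c != "species"]
    agg = {c: "mean" for c in numeric} | {c: "first" for c in other}
    out = table.groupby("species", as_index=False, sort=True).agg(agg)
    return out[[c for c in table.columns if c in out.columns]]
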