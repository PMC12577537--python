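"""Synthetic campaign generator with a ground-truth ledger.

Generates a complete virtual library campaign end-to-end: building blocks
sampled from built-in vocabularies, the Ugi product matrix, logistic
precipitation outcomes driven by the five normalized descriptors, NMR
purities from a two-component Beta mixture, two-year survival as a
per-compound Bernoulli state shared by both platforms, and per-platform /
per-mode centroided peak lists with ppm-scale mass error, lognormal
intensities, and mode-dependent Poisson background noise (positive-mode
spectra are noisier than negative-mode ones, mimicking the elevated TIC the
real instruments show). Every observable derives from the ledger plus
noise, so downstream detection, agreement and modelling stages can be
tested against exact truth without any instrument files.

Calibration of the two free intercepts is part of the generating process:
the logistic intercept is set by bisection so the expected precipitation
rate matches the campaign target (default 1612/2551), and the purity
mixture weight is solved in closed form so the expected fraction of
precipitates exceeding 80% purity matches the retained-library target
(default 1235/1612).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import optimize, stats
from scipy.special import expit

from . import _vocab
from .chem_enum import (
    DESCRIPTOR_NAMES,
    BuildingBlock,
    UgiProduct,
    compute_descriptors,
    enumerate_library,
    normalize_01,
    products_to_frame,
    write_building_blocks_csv,
)
from .detection import DEFAULT_ADDUCTS, PeakList, adduct_mz, write_peaklists_csv
from .plate_io import PlateMap, WellAddress, reformat_96_to_384, write_plate_csv
from .precip_model import label_outcome

__all__ = [
    "Campaign",
    "SimulationConfig",
    "calibrate_logistic_intercept",
    "calibrate_purity_weight",
    "gen_building_blocks",
    "simulate_campaign",
    "simulate_peaklists",
    "simulate_precipitation",
    "simulate_purity",
    "simulate_survival",
    "write_campaign",
]

PLATFORMS = ("AEMS", "UPLC-MS")
MODES = ("positive", "negative")


class SimulationConfig(BaseModel):
    """All knobs of the synthetic campaign; defaults are the study conditions."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n_aldehydes: int = Field(52, ge=0)
    n_isocyanides: int = Field(49, ge=0)

    #: logistic coefficients on 0-1 normalized descriptors
    precip_beta: dict[str, float] = {
        "slogp": 2.5, "topopsa": -1.5, "smr": 1.0, "mw": 0.5, "nhbdon": -0.5,
    }
    #: None -> calibrated by bisection to hit target_precip_rate in expectation
    precip_intercept: float | None = None
    target_precip_rate: float = Field(1612 / 2551, gt=0, lt=1)

    #: Beta(a, b) parameters of the high- and low-purity mixture components
    purity_high: tuple[float, float] = (40.0, 4.0)
    purity_low: tuple[float, float] = (8.0, 4.0)
    #: None -> solved so E[fraction of precipitates with purity > 80] hits target
    purity_weight: float | None = None
    target_green_fraction: float = Field(1235 / 1612, gt=0, lt=1)

    #: per-compound two-year detectability probability (shared by platforms)
    survival_p: float = Field(0.88, ge=0, le=1)

    #: P(adduct responds | compound survived), per platform per adduct name
    adduct_response: dict[str, dict[str, float]] = {
        "AEMS": {"[M+H]+": 0.85, "[M+Na]+": 0.50, "[M-H]-": 0.55},
        "UPLC-MS": {"[M+H]+": 0.70, "[M+Na]+": 0.30, "[M-H]-": 0.45},
    }

    n_uplc_subset: int = Field(384, ge=0)  # UPLC-MS re-measures this many compounds

    ppm_sigma: float = Field(3.0, ge=0)        # mass-error scale, ppm
    noise_rate: dict[str, float] = {"positive": 30.0, "negative": 10.0}
    mass_window: tuple[float, float] = (50.0, 650.0)
    intensity_lognorm: tuple[float, float] = (5.0, 1.0)        # matched peaks
    #: fraction of log-intensity variance shared per compound across
    #: platforms/adducts (compound-specific ionization efficiency)
    intensity_rho: float = Field(0.6, ge=0, le=1)
    noise_intensity_lognorm: tuple[float, float] = (1.5, 0.8)  # background

    @model_validator(mode="after")
    def _check(self):
        for platform, table in self.adduct_response.items():
            for name, p in table.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"adduct_response[{platform}][{name}] not in [0,1]")
        if any(r < 0 for r in self.noise_rate.values()):
            raise ValueError("noise rates must be >= 0")
        if self.noise_rate["positive"] < self.noise_rate["negative"]:
            raise ValueError("positive-mode noise rate must be >= negative-mode rate")
        return self


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def gen_building_blocks(
    config: SimulationConfig,
) -> tuple[list[BuildingBlock], list[BuildingBlock]]:
    """Seeded sampling without replacement from the built-in vocabularies."""
    rng = _rngs(config.seed, 7)[0]
    if config.n_aldehydes > len(_vocab.ALDEHYDE_SMILES):
        raise ValueError(
            f"n_aldehydes={config.n_aldehydes} exceeds vocabulary size "
            f"{len(_vocab.ALDEHYDE_SMILES)}"
        )
    if config.n_isocyanides > len(_vocab.ISOCYANIDE_SMILES):
        raise ValueError(
            f"n_isocyanides={config.n_isocyanides} exceeds vocabulary size "
            f"{len(_vocab.ISOCYANIDE_SMILES)}"
        )
    ald_idx = rng.choice(
        len(_vocab.ALDEHYDE_SMILES), size=config.n_aldehydes, replace=False
    )
    iso_idx = rng.choice(
        len(_vocab.ISOCYANIDE_SMILES), size=config.n_isocyanides, replace=False
    )
    aldehydes = [
        BuildingBlock(
            id=f"ALD{i + 1:03d}",
            role="aldehyde",
            smiles=_vocab.ALDEHYDE_SMILES[j],
            stock_molarity=float(rng.choice([2.5, 5.0])),
        )
        for i, j in enumerate(sorted(ald_idx))
    ]
    isocyanides = [
        BuildingBlock(
            id=f"ISO{i + 1:03d}",
            role="isocyanide",
            smiles=_vocab.ISOCYANIDE_SMILES[j],
            stock_molarity=float(rng.choice([2.5, 5.0])),
        )
        for i, j in enumerate(sorted(iso_idx))
    ]
    return aldehydes, isocyanides


def calibrate_logistic_intercept(eta: np.ndarray, target_rate: float) -> float:
    """Bisect the intercept b0 so that mean(expit(b0 + eta)) == target_rate."""
    return float(
        optimize.brentq(
            lambda b0: expit(b0 + eta).mean() - target_rate, -50.0, 50.0, xtol=1e-10
        )
    )


def simulate_precipitation(
    products: list[UgiProduct],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Bernoulli precipitation flags from a logistic model on descriptors.

    Returns (flags, per-product probabilities, intercept used).
    """
    rng = rng if rng is not None else _rngs(config.seed, 7)[1]
    desc = pd.DataFrame(
        [compute_descriptors(p.smiles).as_dict() for p in products],
        index=[p.id for p in products],
    )
    z = normalize_01(desc[list(DESCRIPTOR_NAMES)])
    beta = np.array([config.precip_beta.get(d, 0.0) for d in DESCRIPTOR_NAMES])
    eta = z.to_numpy() @ beta
    b0 = (
        config.precip_intercept
        if config.precip_intercept is not None
        else calibrate_logistic_intercept(eta, config.target_precip_rate)
    )
    prob = expit(b0 + eta)
    flags = rng.random(len(products)) < prob
    return flags, prob, b0


def calibrate_purity_weight(config: SimulationConfig) -> float:
    """Mixture weight w with w*P_hi(>80%) + (1-w)*P_lo(>80%) = green target."""
    if config.purity_weight is not None:
        return config.purity_weight
    p_hi = float(stats.beta.sf(0.8, *config.purity_high))
    p_lo = float(stats.beta.sf(0.8, *config.purity_low))
    w = (config.target_green_fraction - p_lo) / (p_hi - p_lo)
    if not 0 <= w <= 1:
        raise ValueError(
            f"green-fraction target {config.target_green_fraction} unreachable "
            f"with components P_hi={p_hi:.3f}, P_lo={p_lo:.3f}"
        )
    return w


def simulate_purity(
    n: int, config: SimulationConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """NMR purity (0-100%) from the two-component Beta mixture."""
    rng = rng if rng is not None else _rngs(config.seed, 7)[2]
    w = calibrate_purity_weight(config)
    hi = rng.random(n) < w
    out = np.where(
        hi,
        rng.beta(*config.purity_high, size=n),
        rng.beta(*config.purity_low, size=n),
    )
    return 100.0 * out


def simulate_survival(
    n: int, config: SimulationConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Two-year Bernoulli survival flags, one per retained compound."""
    rng = rng if rng is not None else _rngs(config.seed, 7)[3]
    return rng.random(n) < config.survival_p


def simulate_peaklists(
    compounds: list[tuple[str, float, str]],
    responses: dict[tuple[str, str], bool],
    platform: str,
    mode: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    latent: dict[str, float] | None = None,
) -> list[PeakList]:
    """One spectrum per well: responding-adduct peaks plus Poisson noise.

    ``compounds`` holds (compound_id, neutral mass, well) triples;
    ``responses`` maps (compound_id, adduct name) -> True ledger flags.
    ``latent`` optionally maps compound id to a standard-normal ionization
    factor shared across platforms/modes, so that per-compound AUCs are
    correlated between platforms (variance fraction ``intensity_rho``).
    """
    lo, hi = config.mass_window
    mu, sigma = config.intensity_lognorm
    rho = config.intensity_rho if latent is not None else 0.0
    nmu, nsigma = config.noise_intensity_lognorm
    out = []
    for cid, mass, well in compounds:
        mzs: list[float] = []
        ints: list[float] = []
        z_shared = latent.get(cid, 0.0) if latent is not None else 0.0
        for adduct in DEFAULT_ADDUCTS:
            if adduct.polarity != mode:
                continue
            if not responses.get((cid, adduct.name), False):
                continue
            eps = rng.normal(0.0, config.ppm_sigma)
            mzs.append(adduct_mz(mass, adduct) * (1.0 + eps * 1e-6))
            log_i = mu + sigma * (
                np.sqrt(rho) * z_shared + np.sqrt(1.0 - rho) * rng.normal()
            )
            ints.append(float(np.exp(log_i)))
        n_noise = rng.poisson(config.noise_rate[mode])
        if n_noise:
            mzs.extend(rng.uniform(lo, hi, size=n_noise))
            ints.extend(rng.lognormal(nmu, nsigma, size=n_noise))
        out.append(
            PeakList(platform=platform, mode=mode, well=well,
                     mz=np.array(mzs), intensity=np.array(ints))
        )
    return out


def _plate_products(retained_ids: list[str]) -> tuple[list[PlateMap], list[PlateMap]]:
    """Fill 96-well plates row-major, then stamp each group of 4 into 384."""
    plates96: list[PlateMap] = []
    for i in range(0, len(retained_ids), 96):
        plate = PlateMap(plate_id=f"P96-{len(plates96) + 1:02d}", format=96)
        for j, cid in enumerate(retained_ids[i : i + 96]):
            plate.wells[WellAddress(row=j // 12 + 1, column=j % 12 + 1)] = cid
        plates96.append(plate)
    plates384 = [
        reformat_96_to_384(plates96[i : i + 4], plate_id=f"P384-{i // 4 + 1:02d}")
        for i in range(0, len(plates96), 4)
    ]
    return plates96, plates384


@dataclass
class Campaign:
    """A fully simulated campaign plus its ground-truth ledger."""

    config: SimulationConfig
    aldehydes: list[BuildingBlock]
    isocyanides: list[BuildingBlock]
    products: list[UgiProduct]
    reactions: pd.DataFrame          # one row per reaction with outcome + label
    plates96: list[PlateMap]
    plates384: list[PlateMap]
    subset_ids: list[str]            # compounds re-measured by UPLC-MS
    peaklists: dict[tuple[str, str], list[PeakList]]
    ledger: dict

    @property
    def retained_ids(self) -> list[str]:
        return list(self.reactions.loc[self.reactions.label == "green", "product_id"])

    def well_of(self, compound_id: str) -> str:
        for plate in self.plates384:
            for addr, cid in plate.wells.items():
                if cid == compound_id:
                    return f"{plate.plate_id}:{addr.text()}"
        raise KeyError(compound_id)


def simulate_campaign(config: SimulationConfig | None = None) -> Campaign:
    """Run the full generating process for one seeded campaign."""
    config = config or SimulationConfig()
    rngs = _rngs(config.seed, 8)

    aldehydes, isocyanides = gen_building_blocks(config)
    products = enumerate_library(aldehydes, isocyanides)

    precip, precip_prob, intercept = simulate_precipitation(products, config, rngs[1])
    purity = np.full(len(products), np.nan)
    purity[precip] = simulate_purity(int(precip.sum()), config, rngs[2])

    reactions = products_to_frame(products)
    reactions["precipitated"] = precip
    reactions["purity_pct"] = np.round(purity, 2)
    reactions["label"] = [
        label_outcome(bool(p), float(u) if p else None).value
        for p, u in zip(precip, reactions["purity_pct"])
    ]

    retained = list(reactions.loc[reactions.label == "green", "product_id"])
    survived_arr = simulate_survival(len(retained), config, rngs[3])
    survived = dict(zip(retained, map(bool, survived_arr)))

    # UPLC-MS re-measures a seeded representative subset of the retained set
    n_sub = min(config.n_uplc_subset, len(retained))
    subset_ids = sorted(
        np.asarray(retained, dtype=object)[
            rngs[4].choice(len(retained), size=n_sub, replace=False)
        ]
    )

    # per-platform/per-adduct true response flags, conditional on survival
    responses: dict[str, dict[tuple[str, str], bool]] = {p: {} for p in PLATFORMS}
    resp_rng = rngs[5]
    for cid in retained:
        for platform in PLATFORMS:
            for adduct in DEFAULT_ADDUCTS:
                p = config.adduct_response[platform][adduct.name]
                responds = bool(survived[cid]) and bool(resp_rng.random() < p)
                responses[platform][(cid, adduct.name)] = responds

    plates96, plates384 = _plate_products(retained)
    mass_of = dict(zip(reactions.product_id, reactions.monoisotopic_mass))
    well_of: dict[str, str] = {}
    for plate in plates384:
        for addr, cid in plate.wells.items():
            well_of[cid] = f"{plate.plate_id}:{addr.text()}"

    latent_rng = rngs[7]
    latent = {cid: float(latent_rng.normal()) for cid in retained}

    peaks_rng = rngs[6]
    peaklists: dict[tuple[str, str], list[PeakList]] = {}
    for platform in PLATFORMS:
        measured = retained if platform == "AEMS" else subset_ids
        triples = [(cid, float(mass_of[cid]), well_of[cid]) for cid in measured]
        for mode in MODES:
            peaklists[(platform, mode)] = simulate_peaklists(
                triples, responses[platform], platform, mode, config, peaks_rng,
                latent=latent,
            )

    ledger = {
        "intercept": intercept,
        "purity_weight": calibrate_purity_weight(config),
        "products": {
            row.product_id: {
                "precipitated": bool(row.precipitated),
                "purity_pct": None if pd.isna(row.purity_pct) else float(row.purity_pct),
                "label": row.label,
                "survived": survived.get(row.product_id),
                "in_uplc_subset": row.product_id in set(subset_ids),
                "responses": {
                    platform: {
                        adduct.name: responses[platform].get(
                            (row.product_id, adduct.name)
                        )
                        for adduct in DEFAULT_ADDUCTS
                    }
                    for platform in PLATFORMS
                },
            }
            for row in reactions.itertuples(index=False)
        },
    }

    return Campaign(
        config=config,
        aldehydes=aldehydes,
        isocyanides=isocyanides,
        products=products,
        reactions=reactions,
        plates96=plates96,
        plates384=plates384,
        subset_ids=list(subset_ids),
        peaklists=peaklists,
        ledger=ledger,
    )


def write_campaign(campaign: Campaign, outdir) -> dict[str, Path]:
    """Emit the full fixture set as plain-text files; returns path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["building_blocks"] = outdir / "building_blocks.csv"
    write_building_blocks_csv(
        campaign.aldehydes + campaign.isocyanides, paths["building_blocks"]
    )

    paths["reactions"] = outdir / "reactions.csv"
    campaign.reactions.to_csv(paths["reactions"], index=False)

    # which platform measured which compound, and where
    well_of: dict[str, str] = {}
    for plate in campaign.plates384:
        for addr, cid in plate.wells.items():
            well_of[cid] = f"{plate.plate_id}:{addr.text()}"
    measured_rows = [
        {"platform": platform, "compound_id": cid, "well": well_of[cid]}
        for platform in PLATFORMS
        for cid in (campaign.retained_ids if platform == "AEMS" else campaign.subset_ids)
    ]
    paths["measured"] = outdir / "measured.csv"
    pd.DataFrame(measured_rows, columns=["platform", "compound_id", "well"]).to_csv(
        paths["measured"], index=False
    )

    plate_dir = outdir / "plates"
    plate_dir.mkdir(exist_ok=True)
    for plate in campaign.plates96 + campaign.plates384:
        p = plate_dir / f"{plate.plate_id}.csv"
        write_plate_csv(plate, p)
        paths[f"plate:{plate.plate_id}"] = p

    peaks_dir = outdir / "peaklists"
    peaks_dir.mkdir(exist_ok=True)
    for (platform, mode), pls in campaign.peaklists.items():
        tag = platform.replace("-", "").lower()
        p = peaks_dir / f"{tag}_{mode}.csv"
        write_peaklists_csv(pls, p)
        paths[f"peaks:{platform}:{mode}"] = p

    paths["ledger"] = outdir / "ledger.json"
    paths["ledger"].write_text(
        json.dumps(campaign.ledger, indent=1, sort_keys=True) + "\n"
    )

    paths["config"] = outdir / "config.json"
    paths["config"].write_text(
        json.dumps(campaign.config.model_dump(), indent=1, sort_keys=True) + "\n"
    )
    return paths
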