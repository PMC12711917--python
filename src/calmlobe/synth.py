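"""Seeded synthetic-data generators emulating the experimental designs.

Every assay class consumed by the pipeline can be generated here with known
ground truth, at the geometry of the real experiments: 16-point calcium
titrations spanning 40 nM - 8 mM, 384-well anisotropy half-plates with the
38/68 serial-dilution geometry at eight calcium levels, bi-phasic Ca/Ba
current traces on a 10 kHz grid, two-band alpha-helical CD spectra, SCHEMA-
style carrier tables, and sparse gene x cell count matrices with planted
QC-relevant cell populations.

Each generator takes an integer seed, is byte-deterministic given
(seed, parameters), and returns ``(data, truth)`` where ``truth`` is a
JSON-serializable dict sufficient to score any downstream fit.  Default
noise levels: 1% multiplicative for fluorescence/anisotropy readouts, 2% of
peak additive for current traces.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import datasets
from .catalog import VariantRecord
from .ephys import CurrentTrace
from .fits import (
    DILUTION_FACTOR,
    IsothermSeries,
    TitrationCurve,
    ec50_model,
    hill_model,
    stoich_model,
)
from .spectra import CDSpectrum

__all__ = [
    "gen_titration",
    "gen_iq_plate",
    "gen_traces",
    "trace_amplitude_for_f300",
    "gen_carriers",
    "gen_carrier_counts",
    "gen_counts",
    "gen_cd_spectra",
]

#: Human calmodulin, immature numbering (Met1 retained), 149 residues.
CALMODULIN_SEQUENCE = (
    "MADQLTEEQIAEFKEAFSLFDKDGDGTITTKELGTVMRSLGQNPTEAELQDMINEVDADGNGTIDFPEF"
    "LTMMARKMKDTDSEEEIREAFRVFDKDGNGYISAAELRHVMTNLGEKLTDEEVDEMIREADIDGDGQVN"
    "YEEFVQMMTAK"
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# fluorescence titrations


def gen_titration(
    seed: int,
    kd_app: float = 2.0e-6,
    h: float = 2.0,
    fi_span: float = 100.0,
    fi_initial: float = 10.0,
    noise: float = 0.01,
    n_points: int = 16,
    n_replicates: int = 3,
    ca_min: float = 40e-9,
    ca_max: float = 8e-3,
    channel: str = "tyrosine",
) -> tuple[list[TitrationCurve], dict]:
    """Hill-shaped titrations with multiplicative Gaussian noise."""
    rng = np.random.default_rng(seed)
    ca = np.logspace(math.log10(ca_min), math.log10(ca_max), n_points)
    ideal = hill_model(ca, kd_app, h, fi_span, fi_initial)
    curves = [
        TitrationCurve(
            free_ca=ca,
            intensity=ideal * (1.0 + noise * rng.standard_normal(n_points)),
            channel=channel,
            replicate=f"r{i + 1}",
        )
        for i in range(n_replicates)
    ]
    truth = {
        "assay": "titration", "seed": seed, "kd_app": kd_app, "h": h,
        "fi_span": fi_span, "fi_initial": fi_initial, "noise": noise,
        "channel": channel,
    }
    return curves, truth


# ---------------------------------------------------------------------------
# anisotropy plates


def plate_dilution_series(start_conc: float, n_columns: int = 24) -> np.ndarray:
    """Column-wise serial dilution: start at ``start_conc`` (3 ul CaM into
    65 ul buffer), then transfer 38 ul into 30 ul per column (factor 38/68)."""
    return start_conc * DILUTION_FACTOR ** np.arange(n_columns)


def gen_iq_plate(
    seed: int,
    log10_ec50: float = math.log10(300e-9),
    slope: float = 2.0,
    log_kd_span: float = -4.2,
    log_kd_initial: float = math.log10(5e-6),
    fa_span: float = 0.15,
    fa_initial: float = 0.05,
    iq_total: float = 20e-9,
    noise: float = 0.01,
    n_columns: int = 24,
    high_stock: float = 600e-6,
    low_stock: float = 22.7e-6,
    ca_min: float = 3e-9,
    ca_max: float = 400e-6,
) -> tuple[list[IsothermSeries], dict]:
    """Eight-calcium-row anisotropy plate with logistic ground-truth K_D(Ca).

    The four lowest calcium rows use the concentrated calmodulin stock, the
    four highest the dilute one, mirroring the assay's plate layout.
    """
    rng = np.random.default_rng(seed)
    ca_levels = np.logspace(math.log10(ca_min), math.log10(ca_max), 8)
    kd_levels = 10.0 ** ec50_model(
        np.log10(ca_levels), log10_ec50, slope, log_kd_span, log_kd_initial
    )
    series = []
    for i, (ca, kd) in enumerate(zip(ca_levels, kd_levels)):
        stock = high_stock if i < 4 else low_stock
        cam = plate_dilution_series(stock * 3.0 / 68.0, n_columns)
        ideal = stoich_model(cam, kd, fa_span, fa_initial, iq_total)
        fa = ideal * (1.0 + noise * rng.standard_normal(n_columns))
        series.append(
            IsothermSeries(
                cam_total=cam, anisotropy=fa, iq_total=iq_total, free_ca=ca
            )
        )
    truth = {
        "assay": "iq_plate", "seed": seed, "log10_ec50": log10_ec50,
        "slope": slope, "log_kd_span": log_kd_span,
        "log_kd_initial": log_kd_initial, "fa_span": fa_span,
        "fa_initial": fa_initial, "iq_total": iq_total, "noise": noise,
        "ca_levels": ca_levels.tolist(), "kd_levels": kd_levels.tolist(),
    }
    return series, truth


# ---------------------------------------------------------------------------
# current traces


def trace_amplitude_for_f300(
    f300_norm: float, a_ba: float, tau_ca_ms: float, tau_ba_ms: float,
    window_ms: float = 300.0,
) -> float:
    """Calcium inactivating amplitude A_Ca yielding a target normalized f300
    for mono-exponential-plus-plateau kinetics."""
    r_ba = a_ba * math.exp(-window_ms / tau_ba_ms) + 1.0 - a_ba
    r_ca = (1.0 - f300_norm) * r_ba
    return (1.0 - r_ca) / (1.0 - math.exp(-window_ms / tau_ca_ms))


def gen_traces(
    seed: int,
    f300_norm: float = 0.57,
    tau_ca_ms: float = 40.0,
    tau_ba_ms: float = 300.0,
    a_ba: float = 0.15,
    peak_pa: float = 1000.0,
    noise_frac: float = 0.02,
    n_cells: int = 6,
    voltage_mv: float = 30.0,
    fs_khz: float = 10.0,
    pre_ms: float = 20.0,
    step_ms: float = 350.0,
) -> tuple[list[CurrentTrace], dict]:
    """Paired Ca/Ba traces: I(t) = -I_peak*(A*exp(-t/tau) + 1 - A) during
    the step, additive Gaussian noise, calibrated to a target normalized f300."""
    rng = np.random.default_rng(seed)
    a_ca = trace_amplitude_for_f300(f300_norm, a_ba, tau_ca_ms, tau_ba_ms)
    dt = 1.0 / fs_khz
    t = np.arange(0.0, pre_ms + step_ms, dt) - pre_ms
    in_step = t >= 0.0
    traces = []
    for cell in range(n_cells):
        for carrier, a, tau in (("Ca", a_ca, tau_ca_ms), ("Ba", a_ba, tau_ba_ms)):
            i = np.zeros_like(t)
            ts = t[in_step]
            i[in_step] = -peak_pa * (a * np.exp(-ts / tau) + 1.0 - a)
            i += noise_frac * peak_pa * rng.standard_normal(t.size)
            traces.append(
                CurrentTrace(
                    time_ms=t, current_pa=i, carrier=carrier,
                    voltage_mv=voltage_mv, cell_id=f"cell{cell + 1:02d}",
                )
            )
    r_ba = a_ba * math.exp(-300.0 / tau_ba_ms) + 1.0 - a_ba
    r_ca = a_ca * math.exp(-300.0 / tau_ca_ms) + 1.0 - a_ca
    truth = {
        "assay": "traces", "seed": seed, "a_ca": a_ca, "a_ba": a_ba,
        "tau_ca_ms": tau_ca_ms, "tau_ba_ms": tau_ba_ms,
        "r300_ca": r_ca, "r300_ba": r_ba,
        "f300_raw": r_ba - r_ca, "f300_norm": (r_ba - r_ca) / r_ba,
        "noise_frac": noise_frac, "n_cells": n_cells,
    }
    return traces, truth


# ---------------------------------------------------------------------------
# carrier tables


def gen_carrier_counts(
    seed: int,
    n_cases: int = datasets.SCZ_COHORT_SIZE,
    n_controls: int = datasets.CONTROL_COHORT_SIZE,
    control_rate_n: float = 15 / datasets.CONTROL_COHORT_SIZE,
    control_rate_c: float = 5 / datasets.CONTROL_COHORT_SIZE,
    odds_ratio_n: float = 1.0,
    odds_ratio_c: float = 1.0,
    n_sims: int = 1,
) -> pd.DataFrame:
    """Vectorized per-lobe carrier-count draws (for calibration studies)."""
    rng = np.random.default_rng(seed)
    rows = []
    for lobe, rate, orr in (
        ("N-lobe", control_rate_n, odds_ratio_n),
        ("C-lobe", control_rate_c, odds_ratio_c),
    ):
        odds = rate / (1.0 - rate) * orr
        case_rate = odds / (1.0 + odds)
        a = rng.binomial(n_cases, case_rate, size=n_sims)
        c = rng.binomial(n_controls, rate, size=n_sims)
        for s in range(n_sims):
            rows.append(
                {"sim": s, "lobe": lobe, "cases_carriers": int(a[s]),
                 "cases_total": n_cases, "controls_carriers": int(c[s]),
                 "controls_total": n_controls}
            )
    return pd.DataFrame(rows)


def gen_carriers(
    seed: int = 0,
    replication: bool = False,
    **count_kwargs,
) -> tuple[list[VariantRecord], dict[str, int], dict]:
    """Carrier tables with configurable lobe-specific enrichment.

    ``replication=True`` returns the bundled 27-carrier SCHEMA fixture
    (deterministic); otherwise carriers are drawn per cohort and lobe at
    the configured odds and assigned random plausible protein changes.
    """
    if replication:
        records = datasets.schema_carriers()
        truth = {"assay": "carriers", "replication": True,
                 "n_carriers": len(records)}
        return records, datasets.schema_cohort_sizes(), truth

    counts = gen_carrier_counts(seed, n_sims=1, **count_kwargs)
    rng = np.random.default_rng(seed + 1)
    sizes = {
        "SCZ": int(counts["cases_total"].iloc[0]),
        "control": int(counts["controls_total"].iloc[0]),
    }
    records: list[VariantRecord] = []
    k = 0
    for _, row in counts.iterrows():
        lo, hi = (2, 81) if row["lobe"] == "N-lobe" else (82, 149)
        for cohort, n in (("SCZ", row["cases_carriers"]),
                          ("control", row["controls_carriers"])):
            for _ in range(int(n)):
                pos = int(rng.integers(lo, hi + 1))
                ref = CALMODULIN_SEQUENCE[pos - 1]
                alt = ref
                while alt == ref:
                    alt = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
                gene = f"CALM{rng.integers(1, 4)}"
                k += 1
                records.append(
                    VariantRecord(
                        gene=gene, position=pos, ref_aa=ref, alt_aa=alt,
                        cohort=cohort, carrier_id=f"sim{k:04d}",
                        mpc=float(np.round(rng.uniform(0.2, 3.0), 2)),
                    )
                )
    truth = {
        "assay": "carriers", "replication": False, "seed": seed,
        "n_carriers": len(records),
        "counts": counts.drop(columns="sim").to_dict("records"),
    }
    return records, sizes, truth


# ---------------------------------------------------------------------------
# count matrices


def gen_counts(
    seed: int,
    n_genes: int = 7500,
    n_cells: int = 260,
    n_mito: int = 13,
    n_hemoglobin: int = 10,
    n_low_cells: int = 12,
    n_high_cells: int = 5,
    n_hb_cells: int = 35,   # enough that globin genes pass the 30-cell gene filter
    n_mito_cells: int = 10,
    median_detected: int = 2500,
):
    """Sparse count matrix with planted QC-relevant cell populations.

    Gene symbols include ``MT-`` mitochondrial and globin genes; planted
    cells violate, respectively, the low/high detected-gene bounds, the
    hemoglobin-expression rule, and the 15% mitochondrial-fraction cap.
    ``truth`` lists the planted barcodes per class.
    """
    import anndata as ad
    from scipy import sparse

    rng = np.random.default_rng(seed)
    hb_names = ["HBA1", "HBA2", "HBB", "HBD", "HBE1",
                "HBG1", "HBG2", "HBM", "HBQ1", "HBZ"][:n_hemoglobin]
    mt_names = [f"MT-G{i}" for i in range(1, n_mito + 1)]
    other = [f"GENE{i:05d}" for i in range(n_genes - n_mito - n_hemoglobin)]
    genes = mt_names + hb_names + other
    mt_idx = np.arange(n_mito)
    hb_idx = np.arange(n_mito, n_mito + n_hemoglobin)
    body_idx = np.arange(n_mito + n_hemoglobin, n_genes)

    barcodes = [f"CELL{i:04d}" for i in range(n_cells)]
    classes = np.array(["ok"] * n_cells, dtype=object)
    special = rng.choice(
        n_cells, size=n_low_cells + n_high_cells + n_hb_cells + n_mito_cells,
        replace=False,
    )
    low = special[:n_low_cells]
    high = special[n_low_cells:n_low_cells + n_high_cells]
    hbc = special[n_low_cells + n_high_cells:n_low_cells + n_high_cells + n_hb_cells]
    mito_heavy = special[n_low_cells + n_high_cells + n_hb_cells:]
    classes[low], classes[high] = "low_genes", "high_genes"
    classes[hbc], classes[mito_heavy] = "hemoglobin", "high_mito"

    rows, cols, vals = [], [], []
    for cell in range(n_cells):
        cls = classes[cell]
        if cls == "low_genes":
            n_det = int(rng.integers(150, 700))
        elif cls == "high_genes":
            # detect nearly every gene (violates the upper bound at the
            # default accession-like gene count)
            n_det = int(rng.integers(int(0.94 * n_genes), n_genes - 10))
        else:
            n_det = int(np.clip(rng.lognormal(math.log(median_detected), 0.25),
                                900, 6800))
        pool = body_idx if cls != "high_genes" else np.arange(n_genes)
        idx = rng.choice(pool, size=min(n_det, pool.size), replace=False)
        counts = rng.poisson(1.2, size=idx.size) + 1
        # baseline mitochondrial content ~5% of counts for normal cells
        if cls != "high_genes":
            mito_counts = rng.poisson(
                0.05 * counts.sum() / n_mito, size=n_mito
            )
            idx = np.concatenate([idx, mt_idx])
            counts = np.concatenate([counts, mito_counts])
        if cls == "high_mito":
            boost = int(0.5 * counts.sum())  # push fraction well above 15%
            extra = rng.multinomial(boost, np.full(n_mito, 1.0 / n_mito))
            counts[-n_mito:] += extra
        if cls == "hemoglobin":
            idx = np.concatenate([idx, hb_idx[:2]])
            counts = np.concatenate([counts, rng.poisson(5, size=2) + 1])
        keep = counts > 0
        rows.extend([cell] * int(keep.sum()))
        cols.extend(idx[keep].tolist())
        vals.extend(counts[keep].tolist())

    x = sparse.coo_matrix(
        (vals, (rows, cols)), shape=(n_cells, n_genes), dtype=np.int64
    ).tocsr()
    x.sum_duplicates()
    adata = ad.AnnData(X=x)
    adata.var_names = genes
    adata.obs_names = barcodes
    adata.obs["planted_class"] = classes
    truth = {
        "assay": "counts", "seed": seed,
        "low_cells": [barcodes[i] for i in low],
        "high_cells": [barcodes[i] for i in high],
        "hemoglobin_cells": [barcodes[i] for i in hbc],
        "high_mito_cells": [barcodes[i] for i in mito_heavy],
    }
    return adata, truth


# ---------------------------------------------------------------------------
# CD spectra


def gen_cd_spectra(
    seed: int,
    depth_208: float = -11.0e3,
    depth_222: float = -10.0e3,
    calcium_depth_scale: float = 1.3,
    width_nm: float = 9.0,
    noise: float = 50.0,
    concentration: float = 20e-6,
    path_cm: float = 0.1,
) -> tuple[dict[str, CDSpectrum], dict]:
    """Two-negative-Gaussian alpha-helical template spectra (apo + calcium).

    A descriptor-level stand-in, not a physical band-shape model: band
    depths are in MRE units and calcium deepens both bands by a common
    scale (calcium binding increases helical order).
    """
    rng = np.random.default_rng(seed)
    wl = np.arange(190.0, 260.0 + 0.25, 0.5)

    def template(d208, d222):
        return d208 * np.exp(-((wl - 208.0) ** 2) / (2 * width_nm ** 2)) + \
               d222 * np.exp(-((wl - 222.0) ** 2) / (2 * width_nm ** 2))

    spectra = {}
    for cond, scale in (("apo", 1.0), ("calcium", calcium_depth_scale)):
        theta = template(depth_208 * scale, depth_222 * scale)
        theta = theta + noise * rng.standard_normal(wl.size)
        spectra[cond] = CDSpectrum(
            wavelengths=wl, theta=theta, condition=cond,
            concentration=concentration, path_cm=path_cm, units="mre",
        )
    truth = {
        "assay": "cd", "seed": seed, "depth_208": depth_208,
        "depth_222": depth_222, "calcium_depth_scale": calcium_depth_scale,
        "width_nm": width_nm, "noise": noise,
    }
    return spectra, truth
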