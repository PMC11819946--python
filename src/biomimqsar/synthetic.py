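"""Synthetic compound panels, retention data and hemolysis curves.

The generator emulates the statistical structure the analysis pipeline
assumes for a phenoxyacetic-acid congener panel:

* descriptors in realistic envelopes (MW 166-293 g/mol, TPSA 46.5-95.4 A^2,
  alpha 16.3-33.8 A^3, HBD 1-2, HBA 3-6, NRB 3-7) with two correlated
  blocks — an electronic block {TPSA, HBD+HBA} (|r| ~ 0.96) and a
  structural block {MW, alpha, NRB} (mean |r| ~ 0.84);
* a Collander chain: log k_IAM linear in logP_ow, and
  log k_BMC = a*log k_IAM + b + N(0, sigma) with a=0.437, b=0.684,
  sigma=0.1062 by default;
* linear three-descriptor responses for the five endpoints, with positive
  effects of lipophilicity and polarizability and a negative effect of
  HBD+HBA (for HC50: positive lipophilicity and MW, negative HBA);
* one deliberately extreme compound ("12", logP_ow = 6.535) acting as a
  high-leverage point, switchable off;
* monotone probit hemolysis curves on the standard ten-concentration assay
  grid (250-4000 uM) with known HC50.

Each block is driven by one latent uniform per compound: the integer
descriptors are quantized from the latent and the continuous partners are
linear maps of the (quantized) block variable plus Gaussian noise whose SD
is solved analytically from the target correlation, so the discrete
marginals never break the intended block structure.  All randomness flows
from the single seed in the spec.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError
from .hemolysis import HemolysisCurve
from .io_tables import CompoundPanel, DatasetBundle
from .retention import RetentionRecord

__all__ = ["SimulationSpec", "gen_panel", "gen_retention", "gen_hemolysis", "gen_bundle"]

ENVELOPES = {
    "MW": (166.17, 292.41),
    "TPSA": (46.53, 95.36),
    "alpha": (16.26, 33.76),
    "HBD": (1, 2),
    "HBA": (3, 6),
    "NRB": (3, 7),
    "logP_ow": (0.424, 3.379),
}
EXTREME_LOGP = 6.535
ASSAY_GRID = (250.0, 500.0, 750.0, 1000.0, 1250.0, 1500.0, 1750.0, 2000.0, 3000.0, 4000.0)


def _default_endpoints() -> dict:
    # (intercept, {predictor: coefficient}, noise SD); signs follow the
    # expected physics: barriers are crossed by lipophilic, polarizable,
    # weakly H-bonding molecules; hemolytic potency falls with lipophilicity
    # and size and rises with acceptor count.
    return {
        "logP_wpc": (1.5, {"logk_BMC": 2.0, "alpha": 0.06, "HBD_HBA": -0.45}, 0.10),
        "logKp": (-6.0, {"logk_BMC": 1.2, "alpha": 0.05, "HBD_HBA": -0.30}, 0.10),
        "logP_wHSA": (-1.0, {"logk_BMC": 1.0, "alpha": 0.04, "HBD_HBA": -0.20}, 0.08),
        "logBB": (-0.3, {"logk_IAM": 0.5, "alpha": 0.02, "HBD_HBA": -0.10}, 0.05),
        "HC50": (1200.0, {"logk_BMC": 180.0, "MW": 2.0, "HBA": -80.0}, 30.0),
    }


@dataclass
class SimulationSpec:
    """All knobs of the generator; defaults define the study conditions."""

    n_compounds: int = 29
    seed: int = 0
    r_electronic: float = 0.96    # target |r| between TPSA and HBD+HBA
    r_structural: float = 0.84    # target mean pairwise |r| among MW, alpha, NRB
    collander_slope: float = 0.437
    collander_intercept: float = 0.684
    collander_sigma: float = 0.1062
    logk_iam_sigma: float = 0.10  # noise of log k_IAM around the logP_ow line
    endpoint_coefficients: dict = field(default_factory=_default_endpoints)
    extreme_compound: bool = True  # plant compound "12" at logP_ow = 6.535
    # retention emission
    t0: float = 1.0               # dead time, minutes
    t_sigma: float = 0.002        # relative replicate noise on t_r
    n_replicates: int = 3
    # hemolysis emission
    hc50_range: tuple[float, float] = (1000.0, 2000.0)
    probit_slope: float = 3.0     # probits per decade of concentration
    hemolysis_noise_pct: float = 2.0  # replicate noise, % of blank-control span
    concentrations: tuple[float, ...] = ASSAY_GRID
    abs_blank: float = 0.05
    abs_control: float = 1.00

    def validate(self) -> None:
        for name in ("collander_sigma", "logk_iam_sigma", "t_sigma", "hemolysis_noise_pct"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be nonnegative")
        for name in ("r_electronic", "r_structural"):
            if not 0 <= getattr(self, name) < 1:
                raise DomainError(f"{name} must be in [0, 1)")
        if np.any(np.diff(self.concentrations) <= 0):
            raise DomainError("concentration grid must be strictly increasing")
        for _, (_, _, sigma) in self.endpoint_coefficients.items():
            if sigma < 0:
                raise DomainError("endpoint noise SD must be nonnegative")
        if self.n_compounds < 6:
            raise DomainError("need at least 6 compounds")


def _noise_sd(linear_sd: float, r: float) -> float:
    """SD of additive Gaussian noise giving correlation r with the linear part."""
    if r <= 0:
        return np.inf
    return linear_sd * np.sqrt(1.0 / r**2 - 1.0)


def gen_panel(spec: SimulationSpec) -> tuple[CompoundPanel, dict]:
    """Generate a compound panel plus the record of generating parameters."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_compounds

    # electronic block: one latent uniform -> integer HBD/HBA, TPSA linear in the sum
    u_e = rng.uniform(size=n)
    hba = 3 + np.floor(4 * u_e).astype(int)
    hbd = 1 + (u_e > 0.5).astype(int)
    s = hbd + hba  # takes values 4, 5, 7, 8 with equal probability; var 2.5
    lo_t, hi_t = ENVELOPES["TPSA"]
    tpsa_lin = lo_t + (s - 4) / 4.0 * (hi_t - lo_t)
    lin_sd_t = (hi_t - lo_t) / 4.0 * np.sqrt(2.5)
    tpsa = np.clip(tpsa_lin + rng.normal(0, _noise_sd(lin_sd_t, spec.r_electronic), n), lo_t, hi_t)

    # structural block: NRB latent; pairwise r solves (2r + r^2)/3 = target mean
    u_s = rng.uniform(size=n)
    nrb = 3 + np.floor(5 * u_s).astype(int)  # uniform {3..7}, var 2
    r_pair = -1.0 + np.sqrt(1.0 + 3.0 * spec.r_structural)
    lo_m, hi_m = ENVELOPES["MW"]
    mw_lin = lo_m + (nrb - 3) / 4.0 * (hi_m - lo_m) * 0.85
    lin_sd_m = (hi_m - lo_m) * 0.85 / 4.0 * np.sqrt(2.0)
    mw = np.clip(mw_lin + rng.normal(0, _noise_sd(lin_sd_m, r_pair), n), lo_m, hi_m)
    lo_a, hi_a = ENVELOPES["alpha"]
    a_lin = lo_a + (nrb - 3) / 4.0 * (hi_a - lo_a) * 0.85
    lin_sd_a = (hi_a - lo_a) * 0.85 / 4.0 * np.sqrt(2.0)
    alpha = np.clip(a_lin + rng.normal(0, _noise_sd(lin_sd_a, r_pair), n), lo_a, hi_a)

    # lipophilicity and the Collander chain
    lo_p, hi_p = ENVELOPES["logP_ow"]
    logp = lo_p + rng.uniform(size=n) * (hi_p - lo_p)
    extreme_id = None
    if spec.extreme_compound and n >= 12:
        logp[11] = EXTREME_LOGP
        extreme_id = "12"
    logk_iam = (logp - 2.010) / 1.439 + rng.normal(0, spec.logk_iam_sigma, n)
    logk_bmc = (
        spec.collander_slope * logk_iam
        + spec.collander_intercept
        + rng.normal(0, spec.collander_sigma, n)
    )
    pka = rng.uniform(2.8, 4.2, n)

    frame = pd.DataFrame(
        {
            "compound_id": [str(i + 1) for i in range(n)],
            "name": [f"congener-{i + 1}" for i in range(n)],
            "MW": mw,
            "TPSA": tpsa,
            "alpha": alpha,
            "HBD": hbd,
            "HBA": hba,
            "NRB": nrb,
            "logP_ow": logp,
            "pKa": pka,
            "logk_IAM": logk_iam,
            "logk_BMC": logk_bmc,
        }
    )
    frame["HBD_HBA"] = frame["HBD"] + frame["HBA"]

    truth: dict = {
        "seed": spec.seed,
        "collander": {
            "slope": spec.collander_slope,
            "intercept": spec.collander_intercept,
            "sigma": spec.collander_sigma,
        },
        "extreme_compound": extreme_id,
        "endpoints": {},
    }
    for name, (b0, coefs, sigma) in spec.endpoint_coefficients.items():
        y = np.full(n, float(b0))
        for pred, beta in coefs.items():
            y = y + beta * frame[pred].to_numpy(dtype=float)
        if sigma > 0:
            y = y + rng.normal(0, sigma, n)
        frame[name] = y
        truth["endpoints"][name] = {"intercept": b0, "coef": dict(coefs), "sigma": sigma}
    if "HC50" in frame.columns:
        frame["HC50"] = np.clip(frame["HC50"], 200.0, None)

    return CompoundPanel(frame), truth


def gen_retention(panel: CompoundPanel, spec: SimulationSpec) -> list[RetentionRecord]:
    """Emit triplicate retention times consistent with the panel's log k values.

    t_r = t_0 (1 + 10^{log k}) (1 + eps), eps ~ N(0, t_sigma) per replicate,
    so with t_sigma = 0 the log_k transform round-trips exactly.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, 1])
    records = []
    for system, col in (("IAM", "logk_IAM"), ("BMC", "logk_BMC")):
        for cid, lk in zip(panel.frame["compound_id"], panel.frame[col]):
            base = spec.t0 * (1.0 + 10.0**lk)
            eps = rng.normal(0, spec.t_sigma, spec.n_replicates) if spec.t_sigma > 0 else np.zeros(spec.n_replicates)
            records.append(
                RetentionRecord(
                    compound_id=cid,
                    system=system,
                    t_r=list(base * (1.0 + eps)),
                    t_0=spec.t0,
                )
            )
    return records


def gen_hemolysis(
    spec: SimulationSpec, panel: CompoundPanel | None = None
) -> tuple[list[HemolysisCurve], dict[str, float]]:
    """Probit-model hemolysis curves with known HC50 per compound.

    If a panel with an HC50 column is given, its values (clipped to the
    spec's HC50 range) are the truths; otherwise truths are drawn uniformly
    from that range for n_compounds synthetic ids.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, 2])
    if panel is not None and "HC50" in panel.frame.columns:
        ids = panel.frame["compound_id"].tolist()
        true_hc50 = np.clip(panel.frame["HC50"].to_numpy(dtype=float), *spec.hc50_range)
    else:
        ids = [str(i + 1) for i in range(spec.n_compounds)]
        true_hc50 = rng.uniform(*spec.hc50_range, size=spec.n_compounds)
    conc = np.asarray(spec.concentrations, dtype=float)
    span = spec.abs_control - spec.abs_blank
    noise_sd = spec.hemolysis_noise_pct / 100.0 * span
    curves = []
    for cid, hc in zip(ids, true_hc50):
        if not conc[0] <= hc <= conc[-1]:
            warnings.warn(f"{cid}: true HC50 {hc:.0f} uM outside the assay grid (extrapolation)")
        p = 100.0 * stats.norm.cdf(spec.probit_slope * (np.log10(conc) - np.log10(hc)))
        mean_abs = spec.abs_blank + p / 100.0 * span
        noise = (
            rng.normal(0, noise_sd, (len(conc), spec.n_replicates))
            if noise_sd > 0
            else np.zeros((len(conc), spec.n_replicates))
        )
        curves.append(
            HemolysisCurve(
                compound_id=cid,
                concentrations=conc,
                absorbances=mean_abs[:, None] + noise,
                abs_blank=spec.abs_blank,
                abs_control=spec.abs_control,
            )
        )
    return curves, {cid: float(hc) for cid, hc in zip(ids, true_hc50)}


def gen_bundle(spec: SimulationSpec) -> tuple[DatasetBundle, dict]:
    """Full synthetic study: panel + retention records + hemolysis curves."""
    panel, truth = gen_panel(spec)
    retention = gen_retention(panel, spec)
    hemolysis, true_hc50 = gen_hemolysis(spec, panel)
    truth["hc50"] = true_hc50
    bundle = DatasetBundle(
        panel=panel,
        retention=retention,
        hemolysis=hemolysis,
        provenance=f"synthetic (seed={spec.seed})",
    )
    return bundle, truth
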