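"""End-to-end simulation protocol over a network ensemble.

For a chosen parameter regime, the protocol generates a bipartite network
ensemble spanning a grid of connectance and nestedness, fixes the mutualistic
strength with the ensemble stability policy, assembles several community
realizations per network, and records for each one the effective-competition
summary, the predicted critical perturbation amplitude and (optionally) the
amplitude measured by direct integration.  Failures of individual networks or
realizations are isolated, logged and reported in the output table rather
than aborting the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .community import MetaParameters, assemble_community, RegimeViolationError
from .config import PRESETS
from .critical import rho_crit_closed_form
from .effective import effective_system, DegenerateSystemError
from .linearize import choose_gamma0, equivalent_lv, local_stability
from .networks import (
    describe,
    make_study_ensemble,
    write_incidence,
    write_manifest,
)
from .stability import measure_delta_c, predict_delta_c

logger = logging.getLogger(__name__)

__all__ = ["ProtocolSettings", "run_protocol", "summarize_results"]


@dataclass
class ProtocolSettings:
    """Knobs of one protocol run (reduced sizes keep desk runs tractable)."""

    preset: str = "A"
    n_networks: int = 12
    s_plants: int = 21
    s_animals: int = 20
    kappa_base: float = 0.15
    n_realizations: int = 2
    n_perturbations: int = 30
    measure: bool = False  # direct integration is the expensive path
    measure_deltas: tuple[float, ...] = (0.05, 0.1, 0.2, 0.4, 0.8, 1.6)
    max_swaps: int = 20_000
    gamma0_policy: bool = True


def _spawn_seeds(rng_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(rng_seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def run_protocol(
    settings: ProtocolSettings,
    rng_seed: int = 0,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Run the full protocol; returns one row per (network, realization).

    Columns cover the network descriptors, the regime meta-parameters, the
    per-guild effective competition and feasibility threshold, the predicted
    critical amplitude (and the measured one when ``measure``), the
    closed-form critical direct competition of the topology, and a ``status``
    column ("ok" or the failure reason).  With ``out_dir`` the table, the
    network incidences and a JSON summary are written out.
    """
    preset = PRESETS[settings.preset]
    seeds = _spawn_seeds(rng_seed, 3)
    ensemble = make_study_ensemble(
        n_networks=settings.n_networks,
        s_plants=settings.s_plants,
        s_animals=settings.s_animals,
        kappa_base=settings.kappa_base,
        rng_seed=seeds[0],
        max_swaps=settings.max_swaps,
    )
    meta = MetaParameters.from_preset(preset)
    if settings.gamma0_policy:
        gamma0 = choose_gamma0(
            [net for net, _ in ensemble], meta,
            frac=preset.gamma0_policy_frac,
            rng_seed=seeds[1], fallback=preset.gamma0,
        )
    else:
        gamma0 = preset.gamma0
    meta = MetaParameters.from_preset(preset, gamma0=gamma0)
    logger.info("regime %s: gamma0 = %.4g", preset.label, gamma0)

    regime = "weak_strong" if meta.mutualism == "obligatory_animals" else "weak"
    run_seeds = _spawn_seeds(seeds[2], len(ensemble) * settings.n_realizations)
    rows = []
    for net_idx, (net, net_meta) in enumerate(ensemble):
        d = describe(net)
        try:
            rc = rho_crit_closed_form(net, regime=regime)
            rc_val, rc_flag = rc.rho_c, rc.censored
        except ValueError as exc:
            logger.warning("network %d: closed form failed: %s", net_idx, exc)
            rc_val, rc_flag = np.nan, "error"
        for rep in range(settings.n_realizations):
            seed = run_seeds[net_idx * settings.n_realizations + rep]
            row = {
                "network_id": net_idx, "realization": rep, "seed": seed,
                "kappa": d.connectance,
                "nu_plants": d.nestedness_plants,
                "nu_animals": d.nestedness_animals,
                "regime": preset.label, "gamma0": gamma0,
                "rho_p": meta.rho_p, "rho_a": meta.rho_a,
                "rho_c_closed": rc_val, "rho_c_flag": rc_flag,
                "status": "ok",
            }
            try:
                com = assemble_community(net, meta, rng_seed=seed)
                lv = equivalent_lv(com)
                stable, lead = local_stability(lv)
                eff = effective_system(lv)
                pred = predict_delta_c(
                    eff, rng_seed=seed + 1,
                    n_reps=settings.n_perturbations,
                )
                row.update(
                    locally_stable=stable, leading_eig=lead,
                    rho_eff_p=eff.plants.rho_eff, rho_eff_a=eff.animals.rho_eff,
                    eta_c_p=eff.plants.eta_c, eta_c_a=eff.animals.eta_c,
                    eta_max_p=eff.plants.eta_max, eta_max_a=eff.animals.eta_max,
                    feasible_p=eff.plants.feasible, feasible_a=eff.animals.feasible,
                    delta_c_pred=pred.delta_c,
                    delta_c_pred_p=pred.delta_c_plants,
                    delta_c_pred_a=pred.delta_c_animals,
                    limiting_guild=pred.limiting_guild,
                    obligatory_correction=pred.correction,
                    phi=pred.phi,
                )
                if settings.measure:
                    m = measure_delta_c(
                        com, np.asarray(settings.measure_deltas),
                        n_reps=settings.n_perturbations, rng_seed=seed + 2,
                    )
                    row.update(delta_c_meas=m.delta_c, delta_c_censored=m.censored)
            except (RegimeViolationError, DegenerateSystemError,
                    AssertionError, FloatingPointError,
                    np.linalg.LinAlgError) as exc:
                logger.warning(
                    "network %d realization %d failed: %s", net_idx, rep, exc
                )
                row["status"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    df = pd.DataFrame(rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "results.csv", index=False)
        write_manifest(ensemble, out / "networks_manifest.csv")
        nets_dir = out / "networks"
        nets_dir.mkdir(exist_ok=True)
        for idx, (net, _) in enumerate(ensemble):
            write_incidence(net, nets_dir / f"network_{idx:03d}.csv")
        summary = summarize_results(df)
        summary["settings"] = asdict(settings)
        summary["rng_seed"] = rng_seed
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
    return df


def summarize_results(df: pd.DataFrame) -> dict:
    """Aggregate a protocol table into a JSON-serializable summary."""
    ok = df[df["status"] == "ok"]
    summary: dict = {
        "n_rows": int(len(df)),
        "n_ok": int(len(ok)),
        "failures": df.loc[df["status"] != "ok", "status"].tolist(),
    }
    if len(ok):
        for col in ("rho_eff_p", "rho_eff_a", "eta_c_p", "eta_c_a",
                    "delta_c_pred", "rho_c_closed"):
            if col in ok:
                vals = ok[col].astype(float)
                summary[col] = {
                    "mean": float(np.nanmean(vals)),
                    "std": float(np.nanstd(vals)),
                }
        if "delta_c_meas" in ok:
            vals = ok["delta_c_meas"].astype(float)
            summary["delta_c_meas"] = {
                "mean": float(np.nanmean(vals)),
                "std": float(np.nanstd(vals)),
            }
            both = ok[["delta_c_pred", "delta_c_meas"]].dropna()
            if len(both) >= 3:
                summary["pred_meas_correlation"] = float(
                    np.corrcoef(both["delta_c_pred"], both["delta_c_meas"])[0, 1]
                )
    return summary
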