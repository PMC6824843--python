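"""End-to-end orchestration: session -> preprocess -> all analyses -> report.

Every stochastic stage consumes an explicit seed from ``StageSeeds`` so a
rerun with the same configuration reproduces the report bit-for-bit.  Stage
logging records the neuron counts entering each inclusion rule (load
sensitivity, per-context fit significance) so the filtering funnel is
auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import correlations as corr
from . import onsets as ons
from . import subspace as sub
from . import tuning as tun
from .core import EpochWindows, Session, read_session, write_report, write_session
from .preprocess import (
    build_context_matrices,
    epoch_means,
    smooth_spike_trains,
)
from .simulate import SimConfig, simulate_session

logger = logging.getLogger(__name__)

__all__ = ["StageSeeds", "PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class StageSeeds:
    """Explicit seed per stochastic stage (all required)."""

    simulate: int
    rayleigh: int
    correlation_null: int
    alignment_null: int
    orthogonalization: int
    projection_bootstrap: int

    @classmethod
    def from_master(cls, master: int) -> "StageSeeds":
        ss = np.random.SeedSequence(master)
        vals = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]
        return cls(*vals)


@dataclass
class PipelineConfig:
    """Inputs, analysis parameters and seeds for one pipeline run."""

    seeds: StageSeeds
    sim: SimConfig | None = None
    trials_path: str | None = None
    spikes_path: str | None = None
    kernel: str = "postspike"
    gaussian_sd_ms: float = 20.0
    k: int = 10
    d: int = 3
    n_boot: int = 1000
    out_dir: str | None = None

    def validate(self) -> None:
        if self.sim is None and (self.trials_path is None or self.spikes_path is None):
            raise ValueError("provide either a SimConfig or trials/spikes paths")
        if self.seeds is None:
            raise ValueError("every stochastic stage needs an explicit seed")

    def config_hash(self) -> str:
        payload = {
            "seeds": asdict(self.seeds),
            "sim": asdict(self.sim) if self.sim else None,
            "trials_path": self.trials_path,
            "spikes_path": self.spikes_path,
            "kernel": self.kernel,
            "gaussian_sd_ms": self.gaussian_sd_ms,
            "k": self.k, "d": self.d, "n_boot": self.n_boot,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _fit_record(f: tun.PlanarFit) -> dict:
    return {
        "neuron_id": f.neuron_id,
        "preferred_angle_deg": f.preferred_angle_deg,
        "magnitude_hz_per_nm": f.magnitude_hz_per_nm,
        "p_value": f.p_value,
        "significant": f.significant,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every analysis stage in dependency order; return the report dict.

    If ``config.out_dir`` is set, writes ``report.json`` (plus the simulated
    session CSVs and per-neuron tables) there.
    """
    config.validate()
    report: dict = {
        "config_hash": config.config_hash(),
        "seeds": asdict(config.seeds),
        "parameters": {
            "kernel": config.kernel, "k": config.k, "d": config.d,
            "n_boot": config.n_boot,
        },
    }

    # --- session -----------------------------------------------------------
    truth = None
    if config.sim is not None:
        sim_cfg = SimConfig(**{**asdict(config.sim), "seed": config.seeds.simulate})
        session, truth = simulate_session(sim_cfg)
        report["session"] = {"source": "simulated", "sim": asdict(sim_cfg)}
    else:
        session = read_session(config.trials_path, config.spikes_path)
        report["session"] = {
            "source": "files",
            "trials_path": str(config.trials_path),
            "spikes_path": str(config.spikes_path),
        }
    report["session"]["n_neurons"] = len(session.neuron_ids)
    report["session"]["n_trials"] = len(session.trials)

    # --- preprocessing ------------------------------------------------------
    logger.info("smoothing %d neurons", len(session.neuron_ids))
    rates = smooth_spike_trains(
        session, kernel=config.kernel, gaussian_sd_ms=config.gaussian_sd_ms
    )
    means = epoch_means(rates, EpochWindows())
    C, I = build_context_matrices(rates)

    # --- tuning -------------------------------------------------------------
    sens = tun.load_sensitivity_anova(means)
    sensitive_ids = [s.neuron_id for s in sens if s.load_sensitive]
    logger.info("%d / %d neurons load-sensitive", len(sensitive_ids), len(sens))
    report["tuning"] = {
        "n_load_sensitive": len(sensitive_ids),
        "fraction_load_sensitive": len(sensitive_ids) / max(len(sens), 1),
    }

    fits = {
        (ctx, ep): tun.fit_planes(means, ctx, ep)
        for ctx in ("contra", "ipsi")
        for ep in ("perturbation", "steady_state")
    }
    sens_set = set(sensitive_ids)
    rng_off = 0
    for (ctx, ep), fl in fits.items():
        fl_sens = [f for f in fl if f.neuron_id in sens_set]
        angles = np.array([f.preferred_angle_deg for f in fl_sens])
        stat = tun.rayleigh_stats(angles, "bimodal")
        p = tun.rayleigh_bootstrap_p(
            angles, "bimodal", n_boot=config.n_boot,
            seed=config.seeds.rayleigh + rng_off,
        )
        rng_off += 1
        report["tuning"][f"{ctx}_{ep}"] = {
            "n_neurons": len(fl_sens),
            "n_significant_fits": int(sum(f.significant for f in fl_sens)),
            "bimodal_R": stat.R,
            "bimodal_axis_deg": stat.axis_deg,
            "bimodal_p": p,
            "seed": config.seeds.rayleigh + rng_off - 1,
        }

    # context tuning change (all load-sensitive neurons)
    for ep in ("perturbation", "steady_state"):
        fc = [f for f in fits[("contra", ep)] if f.neuron_id in sens_set]
        fi = [f for f in fits[("ipsi", ep)] if f.neuron_id in sens_set]
        td = tun.tuning_difference(
            fc, fi, n_boot=config.n_boot, seed=config.seeds.rayleigh + rng_off
        )
        rng_off += 1
        report["tuning"][f"context_difference_{ep}"] = {
            "n_neurons": len(td.neuron_ids), "R": td.R,
            "axis_deg": td.axis_deg, "p": td.p, "seed": td.seed,
        }
    # epoch tuning change per context (both-epoch significant subsets)
    for ctx in ("contra", "ipsi"):
        sig_pert = {f.neuron_id for f in fits[(ctx, "perturbation")] if f.significant}
        sig_ss = {f.neuron_id for f in fits[(ctx, "steady_state")] if f.significant}
        both = sig_pert & sig_ss & sens_set
        fp = [f for f in fits[(ctx, "perturbation")] if f.neuron_id in both]
        fs_ = [f for f in fits[(ctx, "steady_state")] if f.neuron_id in both]
        if len(both) >= 2:
            td = tun.tuning_difference(
                fp, fs_, n_boot=config.n_boot, seed=config.seeds.rayleigh + rng_off
            )
            rng_off += 1
            report["tuning"][f"epoch_difference_{ctx}"] = {
                "n_neurons": len(td.neuron_ids), "R": td.R,
                "axis_deg": td.axis_deg, "p": td.p, "seed": td.seed,
            }

    # magnitude contrast: neurons significant in >= 1 context (perturbation)
    sig_any = {
        f.neuron_id
        for ctx in ("contra", "ipsi")
        for f in fits[(ctx, "perturbation")]
        if f.significant
    } & sens_set
    mc = tun.magnitude_contrast(
        [f for f in fits[("contra", "perturbation")] if f.neuron_id in sig_any],
        [f for f in fits[("ipsi", "perturbation")] if f.neuron_id in sig_any],
    )
    report["magnitude"] = {
        "n_neurons": len(mc.neuron_ids),
        "median_contra_hz_per_nm": mc.median_contra,
        "median_ipsi_hz_per_nm": mc.median_ipsi,
        "median_ratio": mc.median_contra / mc.median_ipsi,
        "wilcoxon_z": mc.wilcoxon_z,
        "wilcoxon_p": mc.wilcoxon_p,
        "fraction_contra_larger": mc.fraction_contra_larger,
    }

    # --- onsets -------------------------------------------------------------
    id_to_idx = {nid: i for i, nid in enumerate(rates.neuron_ids)}
    sens_idx = [id_to_idx[n] for n in sensitive_ids]
    pop = {}
    for ctx in ("contra", "ipsi"):
        res, _trace = ons.population_onset(rates, ctx, sens_idx)
        pop[ctx] = res
    onsets_per = {
        ctx: ons.neuron_onsets(rates, ctx, sens_idx) for ctx in ("contra", "ipsi")
    }
    mags = {
        ctx: {
            f.neuron_id: f.magnitude_hz_per_nm
            for f in fits[(ctx, "perturbation")]
        }
        for ctx in ("contra", "ipsi")
    }
    report["onsets"] = {
        "population_contra_ms": pop["contra"].onset_ms,
        "population_ipsi_ms": pop["ipsi"].onset_ms,
    }
    if pop["contra"].onset_ms is not None and pop["ipsi"].onset_ms is not None:
        report["onsets"]["population_lag_ms"] = (
            pop["ipsi"].onset_ms - pop["contra"].onset_ms
        )
    try:
        oc = ons.onset_contrast(onsets_per["contra"], onsets_per["ipsi"], mags)
        report["onsets"].update(
            {
                "n_paired": len(oc.neuron_ids),
                "median_contra_ms": oc.median_contra_ms,
                "median_ipsi_ms": oc.median_ipsi_ms,
                "wilcoxon_z": oc.wilcoxon_z,
                "wilcoxon_p": oc.wilcoxon_p,
                "r_difference_vs_log_ratio": oc.r_difference_vs_log_ratio,
                "r_magnitude_onset_contra": oc.r_magnitude_onset_contra,
                "r_magnitude_onset_ipsi": oc.r_magnitude_onset_ipsi,
            }
        )
    except ValueError as exc:
        report["onsets"]["paired_contrast"] = f"not computed: {exc}"

    # --- correlations -------------------------------------------------------
    cc = corr.correlation_change(C, I)
    report["correlations"] = {
        "n_pairs": int(cc.abs_delta.size),
        "median_abs_delta": cc.median_abs_delta,
        "nulls": {},
    }
    for off, ctx in enumerate(("contra", "ipsi")):
        null = corr.split_trial_null(
            rates, ctx, C.divisors, n_boot=config.n_boot,
            seed=config.seeds.correlation_null + off,
        )
        report["correlations"]["nulls"][ctx] = {
            "mean": float(null.samples.mean()),
            "sd": float(null.samples.std(ddof=1)),
            "p": null.p_value(cc.median_abs_delta),
            "n_boot": null.n_boot,
            "seed": null.seed,
        }

    # --- subspaces ----------------------------------------------------------
    align = sub.alignment_null(
        C, I, k=config.k, n_boot=config.n_boot, seed=config.seeds.alignment_null
    )
    pca_c = sub.context_pca(C, I, k=config.k)
    pca_i = sub.context_pca(I, C, k=config.k)
    report["subspace"] = {
        "alignment": {
            "a_contra_on_ipsi": align.a_contra_on_ipsi,
            "a_ipsi_on_contra": align.a_ipsi_on_contra,
            "mean_index": align.mean_index,
            "null_mean": align.null_mean,
            "null_sd": align.null_sd,
            "p_mean": align.p_mean,
            "n_boot": align.n_boot,
            "seed": align.seed,
        },
        "variance_captured": {
            "contra_pcs_own": float(pca_c.cumulative_own[-1]),
            "contra_pcs_other": float(pca_c.cumulative_other[-1]),
            "ipsi_pcs_own": float(pca_i.cumulative_own[-1]),
            "ipsi_pcs_other": float(pca_i.cumulative_other[-1]),
        },
    }
    wb = sub.weight_balance_index(
        pca_c.components, pca_i.components, neuron_ids=C.neuron_ids
    )
    report["subspace"]["weight_balance"] = {
        "n_neurons": len(wb.neuron_ids),
        "ks_statistic": wb.ks_statistic,
        "ks_p": wb.ks_p,
    }

    pair = sub.joint_orthogonal_subspaces(
        C.covariance(), I.covariance(), d=config.d,
        seed=config.seeds.orthogonalization,
    )
    report["subspace"]["orthogonal"] = {
        "objective": pair.objective,
        "var_captured": pair.var_captured,
        "d": pair.d,
    }
    for off, ref in enumerate(("contra", "ipsi")):
        pd_res = sub.relative_projection_difference(
            pair, rates, C, I, reference=ref, n_boot=config.n_boot,
            seed=config.seeds.projection_bootstrap + off,
        )
        report["subspace"][f"relative_difference_{ref}"] = {
            "percent": pd_res.value_percent,
            "ci_low": pd_res.ci_low,
            "ci_high": pd_res.ci_high,
            "p": pd_res.p,
            "n_boot": pd_res.n_boot,
            "seed": pd_res.seed,
        }

    # --- peripheral ---------------------------------------------------------
    if session.emg is None:
        report["peripheral"] = {"note": "no EMG/kinematics channels in session"}

    # --- ground-truth recovery summary (simulated sessions only) ------------
    if truth is not None:
        from .simulate import alignment_of_bases

        report["ground_truth"] = {
            "alignment_target": truth.config.alignment,
            "alignment_of_bases": alignment_of_bases(truth.U_contra, truth.U_ipsi),
            "onset_lag_target_ms": truth.onset_ms["ipsi"] - truth.onset_ms["contra"],
            "gain_ratio_target": truth.config.contra_gain_ratio,
        }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if config.sim is not None:
            write_session(session, out / "session")
        import pandas as pd

        pd.DataFrame(
            [
                {**_fit_record(f), "context": ctx, "epoch": ep}
                for (ctx, ep), fl in fits.items()
                for f in fl
            ]
        ).to_csv(out / "planar_fits.csv", index=False)
        pd.DataFrame(
            [
                {
                    "neuron_id": o.neuron_id, "context": ctx,
                    "onset_ms": o.onset_ms, "best_load_index": o.best_load_index,
                }
                for ctx, ol in onsets_per.items()
                for o in ol
            ]
        ).to_csv(out / "onsets.csv", index=False)
        write_report(report, out / "report.json")
    return report
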