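"""End-to-end analysis pipeline: synthesize -> preprocess -> fit -> compare.

The pipeline is configured by a flat mapping (typically loaded from YAML).
All randomness flows from the single session seed. Each stage failure is
re-raised as a :class:`PipelineError` naming the stage.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chair_kinematics import StimulusProtocol, make_trapezoid_profile
from .dynamic_model import ModelParameters
from .exceptions import PipelineError
from .io import write_session
from .linear_fit import compare_epochs, fit_linear_model
from .model_fit import lesion_contrast, optimize_parameters
from .preprocessing import mask_trial, median_velocity_profile, synchronize_trials
from .prior_models import PriorModelSpec, step_comparison
from .sensitivity import sweep_2d
from .synthetic_data import NoiseSpec, generate_session, lesion_surrogate

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "n_trials": 4,
    "protocol": {},
    "pre_params": {},
    "post_scale": {"g_i": 0.38, "g_acc": 0.87},
    "noise": {},
    "conditions": None,
    "fit_model": {"n_starts": 3},
    "sensitivity_grid": 9,
    "run_model_fit": True,
    "run_sensitivity": True,
    "run_comparison": True,
}


def _group_by_condition(trials):
    groups: dict[tuple, list] = {}
    for trial in trials:
        key = tuple(
            trial.meta.get(k) for k in ("animal", "eye", "direction", "distance", "target", "epoch")
        )
        groups.setdefault(key, []).append(trial)
    return groups


def run_pipeline(config: dict | None, outdir) -> dict:
    """Run the full pipeline and write all tables under ``outdir``.

    Returns a report dict with the output paths and stage summaries.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"outdir": str(outdir), "seed": cfg["seed"], "version": __version__}
    log_lines = [f"tvorsim {__version__} pipeline, seed={cfg['seed']}"]
    t_start = time.time()

    def stage(name):
        def wrap(fn):
            try:
                t0 = time.time()
                out = fn()
                log_lines.append(f"{name}: ok ({time.time() - t0:.1f} s)")
                return out
            except Exception as exc:
                log_lines.append(f"{name}: FAILED ({exc})")
                (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
                raise PipelineError(name, exc) from exc

        return wrap

    @stage("synth")
    def trials():
        protocol = StimulusProtocol(**cfg["protocol"])
        pre = ModelParameters(**cfg["pre_params"])
        post = lesion_surrogate(
            pre,
            gi_scale=cfg["post_scale"]["g_i"],
            gacc_scale=cfg["post_scale"]["g_acc"],
        )
        noise = NoiseSpec(**cfg["noise"])
        session = generate_session(
            pre,
            post,
            n_trials=int(cfg["n_trials"]),
            conditions=cfg["conditions"],
            noise=noise,
            seed=int(cfg["seed"]),
            protocol=protocol,
        )
        write_session(session, outdir / "trials", seed=int(cfg["seed"]))
        report["n_trials"] = len(session)
        return session, pre, post

    session, pre_params, post_params = trials

    @stage("preprocess")
    def preprocessed():
        masked = [mask_trial(t) for t in session]
        synced = synchronize_trials(masked)
        profile = median_velocity_profile([t for t in synced if t.meta.get("epoch") == "pre"])
        pd.DataFrame(
            {
                "t": profile.time,
                "median": profile.median,
                "p25": profile.p25,
                "p75": profile.p75,
                "n": profile.n_trials,
            }
        ).to_csv(outdir / "velocity_profile_pre.csv", index=False)
        return synced

    @stage("fit-linear")
    def linear():
        groups = _group_by_condition(preprocessed)
        fits = {key: fit_linear_model(g) for key, g in groups.items()}
        rows = [
            dict(
                zip(("animal", "eye", "direction", "distance", "target", "epoch"), key),
                g_v=f.g_v,
                g_a=f.g_a,
                delta_t_ms=1e3 * f.delta_t,
                residual_ss=f.residual_ss,
                n_samples=f.n_samples,
            )
            for key, f in fits.items()
        ]
        pd.DataFrame(rows).to_csv(outdir / "linear_fits.csv", index=False)
        pre = [f for k, f in fits.items() if k[-1] == "pre"]
        post = [f for k, f in fits.items() if k[-1] == "post"]
        comparison = compare_epochs(pre, post)
        comparison.table.to_csv(outdir / "epoch_ratios.csv", index=False)
        report["linear_fit"] = comparison.summary
        return fits

    _ = linear

    model_fits = None
    if cfg["run_model_fit"]:

        @stage("fit-model")
        def fitted():
            groups = _group_by_condition(preprocessed)
            results = {}
            for key, g in groups.items():
                results[key] = optimize_parameters(
                    g, seed=int(cfg["seed"]), **cfg["fit_model"]
                )
            rows = [
                dict(
                    zip(("animal", "eye", "direction", "distance", "target", "epoch"), key),
                    g_i=r.params.g_i,
                    g_acc=r.params.g_acc,
                    tau_ms=1e3 * r.params.tau_delay,
                    residual_ss=r.residual_ss,
                    converged=r.converged,
                )
                for key, r in results.items()
            ]
            pd.DataFrame(rows).to_csv(outdir / "model_fits.csv", index=False)
            pre = [r for k, r in results.items() if k[-1] == "pre"]
            post = [r for k, r in results.items() if k[-1] == "post"]
            contrast = lesion_contrast(pre, post)
            contrast.table.to_csv(outdir / "lesion_contrast.csv", index=False)
            report["lesion_contrast"] = contrast.summary
            return results

        model_fits = fitted

    if cfg["run_sensitivity"]:

        @stage("sensitivity")
        def sens():
            pre_trials = [t for t in preprocessed if t.meta.get("epoch") == "pre"]
            if model_fits is not None:
                pre_keys = [k for k in model_fits if k[-1] == "pre"]
                base = model_fits[pre_keys[0]].params
                ref = [t for t in pre_trials if _matches(t, pre_keys[0])]
            else:
                base = pre_params
                ref = pre_trials
            n = int(cfg["sensitivity_grid"])
            fracs = np.linspace(-1, 1, n)
            surface = sweep_2d(base, fracs, fracs, ref)
            pd.DataFrame(
                surface.error_percent,
                index=pd.Index(surface.ga_fractions, name="ga_fraction"),
                columns=pd.Index(surface.gv_fractions, name="gv_fraction"),
            ).to_csv(outdir / "error_surface.csv")
            report["sensitivity"] = {"baseline_is_minimum": surface.baseline_is_minimum}
            return surface

        _ = sens

    if cfg["run_comparison"]:

        @stage("compare-models")
        def compare():
            protocol = StimulusProtocol(**cfg["protocol"])
            traj = make_trapezoid_profile(protocol, dt=0.001, pad_before=0.1, pad_after=1.3)
            specs = [PriorModelSpec(m) for m in ("telford", "green_galiana", "angelaki", "proposed")]
            table = step_comparison(specs, traj)
            table.to_csv(outdir / "model_comparison.csv", index=False)
            report["comparison"] = table.to_dict("records")
            return table

        _ = compare

    log_lines.append(f"total: {time.time() - t_start:.1f} s")
    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report


def _matches(trial, key) -> bool:
    names = ("animal", "eye", "direction", "distance", "target", "epoch")
    return tuple(trial.meta.get(k) for k in names) == key
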