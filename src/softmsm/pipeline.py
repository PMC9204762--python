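"""End-to-end pipeline: configuration, stage orchestration, provenance.

The pipeline consumes either a synthetic benchmark specification or a
directory of pre-featurized CSV series and runs: feature preparation ->
bound-frame filtering (holo only) -> multi-split training -> state
alignment -> validation -> observables -> local dynamics -> contacts.
Every output file sits next to a ``provenance.json`` carrying the config
hash, master seed and package version, and a stage whose outputs already
exist is skipped unless forced, making reruns idempotent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import ContactSeries, FeatureSeries, StateAssignment
from .contacts import contact_lifetime, contact_probability
from .dynamics import circular_autocorrelation, ramachandran_entropy, state_entropy
from .featurize import circular_embed
from .msm import (PRESETS, align_states_across_models, filter_bound_frames,
                  make_splits, state_averaged_map, train_assignment_model)
from .observables import (frame_weights, model_ensemble_stats, relaxation_timescales,
                          state_lifetimes, state_populations, transition_rates)
from .synthetic import default_benchmark_spec, make_benchmark_ensemble
from .validate import chapman_kolmogorov, implied_timescales

logger = logging.getLogger("softmsm")


def configure_logging(level: int = logging.INFO) -> None:
    """Structured console logging; numerical warnings surface at WARNING."""
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(levelname)-7s %(name)s: %(message)s",
        datefmt="%H:%M:%S",
    )


@dataclass
class PipelineConfig:
    """Everything needed to rerun an analysis end to end."""

    out_dir: str = "softmsm_out"
    features_dir: str | None = None  # pre-featurized CSV input
    synthetic: bool = True  # use the built-in benchmark generator
    n_trajectories: int = 50
    n_frames: int = 2000
    ligand_resname: str | None = None
    bound_cutoff_nm: float = 0.5
    contact_cutoff_nm: float = 0.45
    lag_ns: float = 5.0
    frame_interval_ps: float = 250.0
    k: int = 2
    preset: str = "desk"
    n_splits: int = 20
    n_models: int = 20
    seed: int = 0
    error_mode: str = "percentile"
    ck_n_max: int = 5
    run_contacts: bool = True

    def __post_init__(self) -> None:
        for name in ("bound_cutoff_nm", "contact_cutoff_nm", "lag_ns",
                     "frame_interval_ps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.preset not in PRESETS:
            raise ValueError(f"preset must be one of {sorted(PRESETS)}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.run_contacts and not self.synthetic and self.ligand_resname is None:
            raise ValueError(
                "contact stage enabled but no ligand selection configured")

    @property
    def lag_frames(self) -> int:
        return max(1, int(round(self.lag_ns * 1000.0 / self.frame_interval_ps)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def hash(self) -> str:
        """Hash of the analysis-defining fields (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_provenance(out: Path, config: PipelineConfig, stage: str) -> None:
    (out / "provenance.json").write_text(json.dumps({
        "stage": stage,
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": __version__,
    }, indent=1))


def _stage_done(out: Path, marker: str) -> bool:
    return (out / marker).exists()


def run_pipeline(config: PipelineConfig, force: bool = False) -> dict:
    """Run every stage and return a report dictionary.

    Stage outputs live under ``out_dir/<stage>/``; stages with existing
    outputs are skipped unless ``force``. Any stage failure is re-raised
    with the stage name attached.
    """
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config.hash(), "seed": config.seed}
    stage = "setup"
    try:
        # ---- input preparation -------------------------------------------
        stage = "featurize"
        t0 = time.time()
        if config.synthetic:
            spec = default_benchmark_spec(config.seed, config.n_trajectories,
                                          config.n_frames)
            bench = make_benchmark_ensemble(spec)
            phi, psi, chi1 = bench.phi, bench.psi, bench.chi1
            contact_series = bench.contacts
            truth = bench.ground_truth
        elif config.features_dir is not None:
            fdir = Path(config.features_dir)
            phi = FeatureSeries.from_csv(fdir / "phi.csv")
            psi = FeatureSeries.from_csv(fdir / "psi.csv")
            chi1 = FeatureSeries.from_csv(fdir / "chi1.csv")
            contact_series = (ContactSeries.from_csv(fdir / "contacts.csv")
                              if (fdir / "contacts.csv").exists() else None)
            truth = None
        else:
            raise ValueError("either synthetic=True or features_dir must be set")
        angles = FeatureSeries(
            [np.concatenate([a, b], axis=1) for a, b in zip(phi.arrays, psi.arrays)],
            list(phi.labels) + list(psi.labels), phi.frame_interval_ps, "rad")
        features = circular_embed(angles)
        logger.info("featurize: %d frames x %d features (%.1f s)",
                    features.n_frames, features.n_features, time.time() - t0)

        # ---- training over splits ----------------------------------------
        stage = "train"
        t0 = time.time()
        train_dir = out_root / "train"
        train_dir.mkdir(exist_ok=True)
        plan = make_splits(features.n_frames, n_splits=config.n_splits,
                           seed=config.seed)
        models = []
        seeds = np.random.SeedSequence(config.seed).spawn(config.n_models)
        for i in range(config.n_models):
            model_seed = int(seeds[i].generate_state(1)[0] % (2**31))
            m = train_assignment_model(
                features, k=config.k, lag_frames=config.lag_frames,
                config=config.preset, split=plan.splits[i % plan.n_splits],
                test_idx=plan.test_idx, seed=model_seed)
            models.append(m)
        logger.info("train: %d models (%.1f s)", len(models), time.time() - t0)

        stage = "align"
        if len(models) > 1:
            maps = [state_averaged_map(m.assignment, features) for m in models]
            perms = align_states_across_models(models, maps)
            models = [m.permute(p) for m, p in zip(models, perms)]

        meta = [{k2: (v if not isinstance(v, dict) else v)
                 for k2, v in m.metadata.items()} for m in models]
        (train_dir / "models.json").write_text(json.dumps(meta, default=str, indent=1))
        _write_provenance(train_dir, config, "train")

        # ---- validation ---------------------------------------------------
        stage = "validate"
        t0 = time.time()
        val_dir = out_root / "validate"
        val_dir.mkdir(exist_ok=True)
        ref = models[0]
        grid = sorted({max(1, config.lag_frames // 4), config.lag_frames // 2,
                       config.lag_frames, 2 * config.lag_frames,
                       4 * config.lag_frames})
        its = implied_timescales(ref.assignment, grid)
        its.to_csv(val_dir / "implied_timescales.csv", index=False)
        ck = chapman_kolmogorov(ref.assignment, config.lag_frames,
                                n_max=config.ck_n_max, seed=config.seed)
        (val_dir / "ck_report.json").write_text(json.dumps({
            "tau_ns": ck.tau_ns,
            "max_deviation": ck.max_deviation,
            "passed": ck.passed,
            "all_passed": ck.all_passed(),
        }, indent=1))
        _write_provenance(val_dir, config, "validate")
        report["ck_all_passed"] = ck.all_passed()
        logger.info("validate: CK pass=%s (%.1f s)", ck.all_passed(), time.time() - t0)

        # ---- observables --------------------------------------------------
        stage = "observables"
        obs_dir = out_root / "observables"
        obs_dir.mkdir(exist_ok=True)
        ts = np.array([relaxation_timescales(m.koopman)[0] for m in models])
        lt = np.array([state_lifetimes(m.koopman) for m in models])
        pops = np.array([state_populations(m.koopman) for m in models])
        rates = np.array([transition_rates(m.koopman) for m in models])
        obs = {}
        if len(models) > 1:
            for name, arr in (("slowest_timescale_ns", ts), ("lifetimes_ns", lt),
                              ("populations", pops), ("rates_per_us", rates)):
                st = model_ensemble_stats(arr, mode=config.error_mode,
                                          seed=config.seed)
                obs[name] = {"mean": np.asarray(st.mean).tolist(),
                             "lower": np.asarray(st.lower).tolist(),
                             "upper": np.asarray(st.upper).tolist()}
        else:
            obs = {"slowest_timescale_ns": {"mean": ts.tolist()},
                   "lifetimes_ns": {"mean": lt[0].tolist()},
                   "populations": {"mean": pops[0].tolist()},
                   "rates_per_us": {"mean": rates[0].tolist()}}
        if truth is not None:
            obs["ground_truth"] = {
                "slowest_timescale_ns": float(truth.true_timescales_ns[0]),
                "lifetimes_ns": truth.true_lifetimes_ns.tolist(),
                "populations": truth.true_populations.tolist(),
            }
        (obs_dir / "observables.json").write_text(json.dumps(obs, indent=1))
        _write_provenance(obs_dir, config, "observables")
        report["observables"] = obs

        # ---- local dynamics ----------------------------------------------
        stage = "dynamics"
        dyn_dir = out_root / "dynamics"
        dyn_dir.mkdir(exist_ok=True)
        w = frame_weights(ref.assignment, ref.koopman.pi, provenance="model0")
        ent = ramachandran_entropy(phi, psi, weights=w)
        pd.DataFrame({"residue": [str(r) for r in ent.residues],
                      "entropy_nats": ent.per_residue}).to_csv(
            dyn_dir / "ramachandran_entropy.csv", index=False)
        s_ent = state_entropy(ref.assignment, weights=w)
        rho = circular_autocorrelation(chi1, config.lag_frames)
        pd.DataFrame({"residue": [str(l) for l in chi1.labels],
                      "rho": rho}).to_csv(dyn_dir / "chi1_autocorrelation.csv",
                                          index=False)
        (dyn_dir / "summary.json").write_text(json.dumps({
            "ramachandran_entropy_total_nats": ent.total,
            "state_entropy_nats": s_ent,
        }, indent=1))
        _write_provenance(dyn_dir, config, "dynamics")
        report["ramachandran_entropy_total_nats"] = ent.total
        report["state_entropy_nats"] = s_ent

        # ---- contacts -----------------------------------------------------
        if config.run_contacts and contact_series is not None:
            stage = "contacts"
            con_dir = out_root / "contacts"
            con_dir.mkdir(exist_ok=True)
            kin = contact_lifetime(contact_series, config.lag_frames)
            kin.to_frame().to_csv(con_dir / "contact_kinetics.csv", index=False)
            _write_provenance(con_dir, config, "contacts")
            report["contact_probability"] = {
                str(l): float(p) for l, p in
                zip(contact_series.labels, contact_probability(contact_series))}
            report["contact_lifetimes_ns"] = {
                str(l): (None if not np.isfinite(t) else float(t))
                for l, t in zip(kin.labels, kin.lifetime_ns)}
            if truth is not None:
                report["true_contact_lifetimes_ns"] = truth.true_contact_lifetimes_ns

        (out_root / "report.json").write_text(json.dumps(report, indent=1))
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
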