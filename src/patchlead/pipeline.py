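"""End-to-end pipeline: synthesize → filter → split → fit LR and LSTM →
reconstruct → delineate → classify → report.

Re-running with the same config and seed reproduces every numeric artifact;
the single global seed fans out to fixed per-stage seeds.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import delineate, diagnose, evaluate, linear, lstm, preprocess, synth
from .config import RunConfig
from .records import write_record

log = logging.getLogger("patchlead")


def _stage_seed(seed: int, stage: int) -> int:
    return (seed * 1000003 + stage * 7919) % (2 ** 31)


def config_to_synth(cfg: RunConfig, seed=None, subject="") -> synth.SynthConfig:
    s = cfg.synth
    paths = tuple(synth.PathologySpec(**p) for p in s.pathologies)
    return synth.SynthConfig(
        duration=s.duration_s, fs=s.fs_hz,
        morphology=synth.default_morphology(s.heart_rate_bpm),
        kappa=s.kappa, pathologies=paths, nonlinearity=s.nonlinearity,
        noise_white_uv=s.noise_white_uv, wander_uv=s.wander_uv,
        wander_hz=s.wander_hz, rr_jitter=s.rr_jitter,
        seed=_stage_seed(cfg.seed, 1) if seed is None else seed,
        subject=subject)


def delineate_and_classify(record, cfg: RunConfig):
    """Detect, delineate and classify one 12-lead record."""
    r = delineate.detect_record_r_peaks(record)
    if r.size == 0:
        raise RuntimeError("no R peaks detected")
    fid = delineate.delineate_waves(record, r)
    params = delineate.extract_parameters(fid, record)
    thr = diagnose.CriteriaThresholds(
        wide_qrs_ms=cfg.diagnose.wide_qrs_ms, st_mv=cfg.diagnose.st_mv,
        st_delay_after_j_s=cfg.diagnose.st_delay_after_j_s,
        q_fraction_of_r=cfg.diagnose.q_fraction_of_r,
        q_duration_ms=cfg.diagnose.q_duration_ms, lvh_mv=cfg.diagnose.lvh_mv)
    labels = diagnose.classify_pathologies(params, fid, record, thr)
    return fid, params, labels


def run_pipeline(cfg: RunConfig, out_dir) -> dict:
    """Execute the full chain and write artifacts under ``out_dir``.

    Returns a dict of the in-memory results (paired recording, models,
    reconstructions, report).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    def tick(stage):
        log.info("%-12s %6.1f s", stage, time.time() - t0)

    paired = synth.synth_paired_recording(config_to_synth(cfg))
    write_record(paired.patch, out / "patch.csv")
    write_record(paired.target, out / "target.csv")
    synth.write_ground_truth(paired.beats, out / "ground_truth.json")
    tick("synth")

    if cfg.filter.enabled:
        patch = preprocess.bandpass(paired.patch, cfg.filter.low_hz,
                                    cfg.filter.high_hz)
        target = preprocess.bandpass(paired.target, cfg.filter.low_hz,
                                     cfg.filter.high_hz)
        paired = synth.PairedRecording(patch=patch, target=target,
                                       beats=paired.beats)
    train, test = preprocess.split_train_test(paired, cfg.split.train_s)
    log.info("split: %.1f s train / %.1f s test", train.patch.duration,
             test.patch.duration)

    lr_model = linear.fit_transform_matrix(train.patch, train.target,
                                           ridge=cfg.lr.ridge)
    lr_recon = linear.apply_transform(lr_model, test.patch)
    (out / "transform.json").write_text(linear.transform_to_json(lr_model))
    write_record(lr_recon, out / "recon_lr.csv")
    tick("fit-lr")

    bundle = lstm.TwelveLeadLSTM(
        n_layers=cfg.lstm.n_layers, hidden=cfg.lstm.hidden,
        window=cfg.window.len_samples, step=cfg.window.step_samples,
        batch_size=cfg.lstm.batch, epochs=cfg.lstm.epochs,
        learning_rate=cfg.lstm.learning_rate,
        predict_step=cfg.lstm.predict_step,
        seed=_stage_seed(cfg.seed, 2))
    bundle.fit(train.patch, train.target)
    lstm_recon = bundle.reconstruct(test.patch)
    lstm.save_bundle(bundle, out / "lstm_bundle.npz")
    write_record(lstm_recon, out / "recon_lstm.csv")
    tick("train-lstm")

    params = {}
    labels = {}
    fids = {}
    for name, rec in (("standard", test.target), ("lr", lr_recon),
                      ("lstm", lstm_recon)):
        try:
            fids[name], params[name], labels[name] = \
                delineate_and_classify(rec, cfg)
        except (RuntimeError, ValueError) as exc:
            # a reconstruction too poor to delineate is reported, not fatal
            log.warning("delineation of %s failed: %s", name, exc)
            fids[name] = params[name] = labels[name] = None
    tick("delineate")

    report = evaluate.build_report(
        test.target, {"lr": lr_recon, "lstm": lstm_recon},
        params={k: v for k, v in params.items() if v is not None})
    report.waveform.to_csv(out / "waveform_metrics.csv",
                           float_format="%.6f")
    report.parameters.to_csv(out / "parameters.csv", float_format="%.6f")
    label_rows = {name: (None if lab is None else
                         {f: bool(v) for f, v in lab.as_dict().items()})
                  for name, lab in labels.items()}
    (out / "labels.json").write_text(
        json.dumps(label_rows, indent=1, sort_keys=True))
    (out / "report.txt").write_text(report.to_text())
    tick("evaluate")

    return {"paired": paired, "train": train, "test": test,
            "lr_model": lr_model, "lr_recon": lr_recon, "bundle": bundle,
            "lstm_recon": lstm_recon, "params": params, "labels": labels,
            "report": report}
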