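"""Deterministic small fixture datasets for tests and documentation."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .calibrate import get_geometry
from .model_order import ThresholdTable
from .simulate import draw_dipoles, make_activity, simulate_recording


def make_fixtures(seed: int, out_dir) -> dict:
    """Write a deterministic fixture bundle and return the paths.

    Contents: a 32-channel array with a 150-point grid pair and its lead
    fields; one noiseless 2-dipole recording; one 0 dB, rho = 0.5 recording
    with a baseline segment; and a small synthetic 5×5 threshold table
    (placeholder values on the calibration grid layout, labelled as such —
    it exercises table plumbing, not calibrated numbers).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lf_sim, lf_recon = get_geometry("desk32")
    paths = {}

    paths["leadfields"] = out / "leadfields_desk32.h5"
    lf_recon.save(paths["leadfields"])

    rng = np.random.default_rng(seed)
    s1, s2, s3, s4 = (int(rng.integers(2**31)) for _ in range(4))

    dip = draw_dipoles(lf_sim, 2, s1, min_separation=0.03)
    act = make_activity(2, 100, 1000.0, rho=0.0, rng_seed=s2)
    rec_clean = simulate_recording(lf_sim, dip, act, snr_db=np.inf, rng_seed=s1)
    paths["recording_noiseless"] = out / "recording_noiseless_q2.h5"
    rec_clean.save(paths["recording_noiseless"])

    dip2 = draw_dipoles(lf_sim, 2, s3, min_separation=0.03)
    act2 = make_activity(2, 100, 1000.0, rho=0.5, rng_seed=s4)
    rec_noisy = simulate_recording(
        lf_sim, dip2, act2, snr_db=0.0, rng_seed=s3, n_baseline=200
    )
    paths["recording_0db"] = out / "recording_0db_rho05_q2.h5"
    rec_noisy.save(paths["recording_0db"])

    table = ThresholdTable(
        snr_grid=np.array([-8.0, -4.0, 0.0, 4.0, 8.0]),
        k_grid=np.arange(1, 6),
        f_th=1.0 + 0.5 * np.add.outer(np.linspace(0.2, 2.0, 5), 1.0 / np.arange(1, 6)),
        metadata={"synthetic": True, "note": "layout fixture, not calibrated values"},
    )
    paths["threshold_table"] = out / "threshold_table_synthetic.json"
    table.save(paths["threshold_table"])
    return {k: str(v) for k, v in paths.items()}
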