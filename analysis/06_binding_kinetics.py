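#!/usr/bin/env python
"""Single-cycle SPR and ELISA saturation fits on simulated data.

Simulates a nanomolar 1:1 interaction (ka = 1e6 /(M s), kd = 1e-3 /s,
Kd = 1 nM) under the five-step single-cycle schedule, fits the kinetic
model with and without noise, and fits a saturation hyperbola over the
0.03-234 nM concentration window.  Noiseless fits recover the rate
constants to machine precision; with 2% noise the recovery stays within
a few percent, and Kd is the ratio kd/ka by construction.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from xlms import bindingaffinity as ba  # noqa: E402
from xlms import synthetic_data as sd  # noqa: E402

OUT = ROOT / "results"


def main():
    OUT.mkdir(exist_ok=True)
    rows = []
    for label, noise in (("noiseless", 0.0), ("2% noise", 2.0)):
        times, r, truth, sched = sd.gen_sensorgram(noise_sd=noise, seed=5, sample_hz=0.2)
        fit = ba.fit_sck(times, r, sched)
        rows.append(
            {
                "condition": label,
                "ka_true": truth.ka, "ka_fit": fit.ka,
                "kd_true": truth.kd, "kd_fit": fit.kd,
                "Kd_fit_nM": fit.Kd * 1e9,
                "ka_rel_err": abs(fit.ka - truth.ka) / truth.ka,
                "kd_rel_err": abs(fit.kd - truth.kd) / truth.kd,
            }
        )
    spr = pd.DataFrame(rows)
    spr.to_csv(OUT / "spr_fit.tsv", sep="\t", index=False)
    print(spr.to_string(index=False))

    # ELISA-style saturation: triplicates over 0.03-234 nM
    rng = np.random.default_rng(9)
    kd_true, bmax = 1.1e-9, 1.8
    conc = np.repeat(np.geomspace(0.03e-9, 234e-9, 8), 3)
    resp = ba.saturation_response(conc, bmax, kd_true) + rng.normal(0, 0.02 * bmax, conc.shape)
    fit = ba.fit_saturation(ba.SaturationCurve(conc, resp, replicates=3))
    print(
        f"\nsaturation fit: Kd = {fit.Kd * 1e9:.2f} nM (true 1.10 nM), "
        f"Bmax = {fit.bmax:.3f} (true {bmax}), reliable = {fit.reliable}"
    )
    pd.DataFrame(
        [{"Kd_nM": fit.Kd * 1e9, "Bmax": fit.bmax, "Kd_stderr_nM": fit.Kd_stderr * 1e9}]
    ).to_csv(OUT / "elisa_fit.tsv", sep="\t", index=False)
    print(f"wrote {OUT / 'spr_fit.tsv'} and {OUT / 'elisa_fit.tsv'}")


if __name__ == "__main__":
    main()
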