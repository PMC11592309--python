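"""Run the whole staging pipeline on a small synthetic cohort.

Six synthetic nights are simulated, decomposed (db4, 4 levels), turned
into 105-dim epoch features and 3x105 windows, and cross-validated with
an LSTM classifier plus HMM correction.  A full-size study (more/longer
nights, 10 folds) uses the same call with different numbers — or the CLI:
`wavesleep run-all --run-dir runs/demo`.
"""

import json
import tempfile

from wavesleep.pipeline import InputConfig, PipelineConfig, SyntheticInput, run

config = PipelineConfig(
    seed=5,
    cv_k=3,
    classifier={"epochs": 20},
    input=InputConfig(
        kind="synthetic",
        synthetic=SyntheticInput(n_nights=6, n_epochs=60),
    ),
)

with tempfile.TemporaryDirectory() as tmp:
    summary = run(config, tmp)

print(json.dumps({k: summary[k] for k in ("raw", "corrected")}, indent=2))
print(f"\n{summary['n_nights']} nights, {summary['n_epochs']} scored epochs, "
      f"{summary['elapsed_seconds']:.0f} s.")
print("'raw' = LSTM predictions; 'corrected' = after HMM Viterbi decoding.")
print("Each block reports the 3-fold mean and SD of accuracy, macro-F1 and kappa.")
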