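"""Shared configuration for the numbered analysis drivers.

One desk-scale herd mirroring the study design (24 Angus-like sires, 28
Xiangxi-like dams, F1 plus backcross/intercross F2, RAD-like noise); every
driver reads/writes under results/.
"""

from pathlib import Path

from crosskin import synth

RESULTS = Path(__file__).resolve().parent.parent / "results"
HERD_DIR = RESULTS / "herd"
SEED = 20240718

HERD_CONFIG = synth.SimulationConfig(
    n_sires=24,
    n_dams=28,
    n_f1=200,
    n_f2_backcross=80,
    n_f2_intercross=20,
    n_loci=2000,
    frac_fixed_divergent=0.3,
    mean_depth=12.0,
    genotype_error_rate=0.002,
    missing_rate=0.05,
    seed=SEED,
)
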