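import numpy as np
import pytest

from rhythmdiff.pipeline import PipelineConfig, run_pipeline

SEED = 0

# truth category -> expected decision-table label (group 1 = test condition B)
TRUTH_TO_LABEL = {
    "arrhythmic_both": "unclassified",
    "rhythmic_unchanged": "rhythmic_both_unchanged",
    "phase_shifted": "rhythmic_both_phase_change",
    "other_changed": "rhythmic_both_other_difference",
    "gained_in_B": "gained_in_g1_only",
    "lost_in_B": "lost_in_g1",
}


def _study_config(outdir, concat=2):
    cfg = PipelineConfig(seed=SEED, outdir=str(outdir))
    cfg.detect.concat = concat
    return cfg


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    """Default end-to-end run: 2000 genes, study-condition fractions, concat ×2."""
    out = tmp_path_factory.mktemp("study_run")
    return run_pipeline(_study_config(out))


@pytest.fixture(scope="session")
def study_run_noconcat(tmp_path_factory):
    """Same simulated dataset (same seed), detection without concatenation."""
    out = tmp_path_factory.mktemp("study_run_noconcat")
    return run_pipeline(_study_config(out, concat=1))


def circ_dist_h(a, b, cycle=24.0):
    d = np.abs(np.asarray(a) - np.asarray(b)) % cycle
    return np.minimum(d, cycle - d)
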