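import pytest

from qsigval.panel import example_panel
from qsigval.plate import SampleRun, WellRecord


@pytest.fixture(scope="session")
def panel():
    return example_panel()


def make_run(panel, ct_by_gene, sample_id="S1", plate_id="P1", hbb=(41.0, 41.0, 41.0),
             clinical=None):
    """Build a SampleRun from per-gene replicate tuples.

    ``ct_by_gene`` maps gene -> scalar (repeated 3x) or an iterable of up to 3
    Cts where None means an undetected well.  ``hbb`` sets the
    contamination-gene replicates the same way.
    """
    wells = []
    entries = dict(ct_by_gene)
    entries[panel.contamination_gene] = hbb
    for gene, cts in entries.items():
        if isinstance(cts, (int, float)):
            cts = (float(cts),) * 3
        for i, ct in enumerate(cts, start=1):
            wells.append(WellRecord(sample_id, gene, i, ct, plate_id))
    return SampleRun(sample_id, plate_id, wells, clinical=clinical)


@pytest.fixture
def clean_run_factory(panel):
    """Runs with every expression gene at a constant Ct (pass-by-construction)."""

    def factory(target_ct=20.0, hk_ct=22.0, **kwargs):
        cts = {g: target_ct for g in panel.targets}
        cts.update({g: hk_ct for g in panel.housekeepers})
        return make_run(panel, cts, **kwargs)

    return factory
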