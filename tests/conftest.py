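import pytest
from hypothesis import HealthCheck, settings

from xlscreen import Peptide, build_reporter_set
from xlscreen.synthdata import SimulationConfig, simulate_run

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

REPORTER_SEQ = "DSVTRQKEPRAPW"
SITE_INDEX = 7  # K43 of the mature carrier protein

# Synthetic carrier context: the real mature sequence is not reproduced
# here; this 68-mer embeds the reporter 13-mer at mature positions 37-49
# (site residue K at 43) between chymotrypsin-compatible flanks.
SYNTHETIC_CARRIER = (
    "RTHSLRYVHTAVSRPGRGEPRFIAVEYVDDTEFVR" "L"
    + REPORTER_SEQ
    + "GSHTIQEISGHEVDAAGNA"
)


@pytest.fixture(scope="session")
def peptide() -> Peptide:
    return Peptide(REPORTER_SEQ, site_index=SITE_INDEX)


@pytest.fixture(scope="session")
def reporter_set(peptide):
    return build_reporter_set(peptide)


@pytest.fixture(scope="session")
def small_run():
    """One deterministic synthetic run (Ac-6-FP planted at 8% AUC ratio)."""
    cfg = SimulationConfig(seed=11, ms1_interval=0.2)
    return simulate_run(cfg)


@pytest.fixture(scope="session")
def carrier_fasta(tmp_path_factory):
    path = tmp_path_factory.mktemp("fasta") / "synthetic_carrier.fasta"
    path.write_text(">synthetic_carrier synthetic context around the "
                    "reporter 13-mer\n" + SYNTHETIC_CARRIER + "\n")
    return path
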