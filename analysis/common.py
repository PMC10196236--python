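"""Shared paths and the study-scale synthetic bundle parameters.

The bundle emulates the study's inputs at desk scale: a ~2x10^5-window
proteome, a ~10x larger microbiome reference, 1,500 interior missense
mutations spread over 30 cases (50 each), genotypes drawn from a small
allele pool, and anchor-dominated binding truths per allele.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "scratch" / "data"     # bulky regenerable inputs
RESULTS = ROOT / "results"           # small summary tables

SEED = 20230505

PROTEOME_KW = dict(n_proteins=700, min_length=150, max_length=450)
MICROBIOME_SCALE = 10.0
N_MUTATIONS = 1500
N_CASES = 30
THRESHOLD = -1.0


def ensure_dirs():
    DATA.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
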