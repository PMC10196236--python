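"""Generate the synthetic study bundle: proteome, microbiome, mutations,
genotypes.  Everything downstream reads these files, so the whole analysis is
reproducible from this one seed."""

import json
from dataclasses import replace

from common import DATA, MICROBIOME_SCALE, N_CASES, N_MUTATIONS, PROTEOME_KW, RESULTS, SEED, ensure_dirs

from neomotif import io as nio
from neomotif.motif_core import window_peptides
from neomotif.synthetic_data import (
    ProteomeSpec,
    gen_genotypes,
    gen_microbiome,
    gen_mutations,
    gen_proteome,
)

ensure_dirs()

spec = ProteomeSpec(**PROTEOME_KW)
proteome = gen_proteome(spec, SEED)
microbiome = gen_microbiome(spec, SEED + 1, scale=MICROBIOME_SCALE)
genotypes = gen_genotypes(N_CASES, seed=SEED + 3, homozygosity_rate=0.1)
cases = list(genotypes.case_id)
mutations = [
    replace(m, case_id=cases[i % len(cases)])
    for i, m in enumerate(gen_mutations(proteome, N_MUTATIONS, SEED + 2, rare_bias=True))
]

nio.write_fasta(proteome, DATA / "proteome.fa")
nio.write_fasta(microbiome, DATA / "microbiome.fa")
nio.write_mutations(mutations, DATA / "mutations.tsv")
nio.write_genotypes(genotypes, DATA / "genotypes.tsv")

n_win_h = sum(len(window_peptides(p, 15)) for p in proteome)
n_win_m = sum(len(window_peptides(p, 15)) for p in microbiome)
manifest = {
    "seed": SEED,
    "n_proteins": len(proteome),
    "proteome_15mer_windows": n_win_h,
    "microbiome_15mer_windows": n_win_m,
    "microbiome_to_proteome_ratio": round(n_win_m / n_win_h, 2),
    "n_mutations": len(mutations),
    "n_cases": N_CASES,
}
(RESULTS / "01_manifest.json").write_text(json.dumps(manifest, indent=1))
print("synthetic bundle written to", DATA)
print(json.dumps(manifest, indent=1))
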