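"""Independent brute-force oracles shared across test modules.

These deliberately avoid the package's fast paths: explicit window objects,
nested loops and per-row reclassification.
"""

from collections import Counter

import pandas as pd

from neomotif.genotype_logic import CLASS_I_SLOTS
from neomotif.motif_core import window_peptides


def brute_force_tally(proteome, motif_class):
    """Nested-loop pentamer tally over explicit windows."""
    width = 9 if motif_class == "I" else 15
    tally = Counter()
    for protein in proteome:
        for w in window_peptides(protein, width):
            if motif_class == "I":
                tally[w.peptide[3:8]] += 1
            else:
                p = w.peptide
                tally[p[4] + p[5] + p[7] + p[9] + p[10]] += 1
    return tally


def make_annotations(rng, n_mutations=20, bound_scale=1.0):
    """Randomized one-case annotation table: 9 registers x 9mer + 15 x 15mer."""
    rows = []
    for m in range(n_mutations):
        pid, pos, alt = f"p{m}", 50 + m, "W"
        for width, n_reg in ((9, 9), (15, 15)):
            for k in range(n_reg):
                if width == 9:
                    pocket = k + 1
                    exposed = pocket in (4, 5, 6, 7, 8)
                else:
                    core = k + 1 - 3
                    pocket = core if 1 <= core <= 9 else -1
                    exposed = pocket in (2, 3, 5, 7, 8)
                row = dict(
                    case_id="c1", protein_id=pid, position=pos, alt_aa=alt,
                    width=width, start=pos - (n_reg - 1) + k, pocket=pocket,
                    exposed=exposed,
                    hppf_mut=int(rng.integers(0, 11)), hppf_wt=int(rng.integers(0, 30)),
                )
                slots = CLASS_I_SLOTS if width == 9 else ("DRB1_1", "DRB1_2")
                for s in slots:
                    row[f"z_mut_{s}"] = float(rng.normal() * bound_scale)
                    row[f"z_wt_{s}"] = float(rng.normal() * bound_scale)
                rows.append(row)
    return pd.DataFrame(rows)


def downselect_brute_force(df, threshold, dual_rule="mutation"):
    """Exhaustive per-peptide reclassification oracle for the cascade rows."""
    df9 = df[df.width == 9]
    df15 = df[df.width == 15]
    zcols9 = [f"z_mut_{s}" for s in CLASS_I_SLOTS]
    dual_keys = set()
    for r in df15.itertuples():
        if r.exposed and min(r.z_mut_DRB1_1, r.z_mut_DRB1_2) <= threshold:
            dual_keys.add((r.protein_id, r.position, r.alt_aa))
    n_binding = n_exposed_binding = n_dual = 0
    for r in df9.itertuples():
        binds = any(getattr(r, c) <= threshold for c in zcols9)
        n_binding += binds
        if binds and r.exposed:
            n_exposed_binding += 1
            if (r.protein_id, r.position, r.alt_aa) in dual_keys:
                n_dual += 1
    return n_binding, n_exposed_binding, n_dual
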