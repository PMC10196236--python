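"""Synthetic inputs with the statistical structure the analysis assumes.

Generators for proteomes (human-like residue composition), microbiome-scale
reference proteomes, interior missense mutation sets, HLA genotypes, and a
known anchor-dominated peptide-binding energy function with lognormal-noise
ic50 training sets.  Everything is a pure function of (spec, seed), so every
downstream stage runs and is testable without any external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .binding_model import BindingPrediction, TrainingExample
from .motif_core import AMINO_ACIDS, AA_INDEX, Mutation, ProteinRecord

#: Approximate residue frequencies of the human proteome.  Tryptophan,
#: cysteine, methionine and histidine are naturally the rarest residues, so
#: mutations toward them tend to create rare pentamer motifs.
HUMAN_LIKE_COMPOSITION: dict[str, float] = {
    "A": 0.070, "R": 0.056, "N": 0.036, "D": 0.047, "C": 0.023,
    "Q": 0.048, "E": 0.071, "G": 0.066, "H": 0.026, "I": 0.043,
    "L": 0.100, "K": 0.057, "M": 0.021, "F": 0.037, "P": 0.063,
    "S": 0.083, "T": 0.053, "W": 0.012, "Y": 0.027, "V": 0.060,
}

RARE_RESIDUES = ("W", "C", "H", "M")

CLASS_I_LOCI = ("A", "A", "B", "B", "C", "C")
GENOTYPE_COLUMNS = ("A1", "A2", "B1", "B2", "C1", "C2", "DRB1_1", "DRB1_2")

DEFAULT_ALLELE_POOL: dict[str, tuple[str, ...]] = {
    "A": ("A*02:01", "A*03:01", "A*24:02", "A*01:01"),
    "B": ("B*07:02", "B*08:01", "B*44:02", "B*35:01"),
    "C": ("C*04:01", "C*07:02", "C*06:02", "C*03:04"),
    "DRB1": ("DRB1*01:01", "DRB1*04:01", "DRB1*07:01", "DRB1*15:01"),
}


def _composition_vector(composition: Optional[dict[str, float]]) -> np.ndarray:
    comp = HUMAN_LIKE_COMPOSITION if composition is None else composition
    p = np.array([comp[aa] for aa in AMINO_ACIDS], dtype=float)
    if (p < 0).any() or p.sum() <= 0:
        raise ValueError("composition probabilities must be non-negative and sum > 0")
    return p / p.sum()


@dataclass
class ProteomeSpec:
    n_proteins: int = 400
    min_length: int = 100
    max_length: int = 400
    composition: Optional[dict[str, float]] = None  # None = human-like
    name: str = "synthetic-proteome"

    def __post_init__(self):
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.min_length < 9 or self.max_length < self.min_length:
            raise ValueError("lengths must satisfy 9 <= min <= max")


def gen_proteome(spec: ProteomeSpec, seed: int) -> list[ProteinRecord]:
    """Random proteome: uniform lengths in [min, max], i.i.d. residues."""
    rng = np.random.default_rng(seed)
    p = _composition_vector(spec.composition)
    aas = np.array(list(AMINO_ACIDS))
    out = []
    lengths = rng.integers(spec.min_length, spec.max_length + 1, size=spec.n_proteins)
    for i, L in enumerate(lengths):
        seq = "".join(aas[rng.choice(20, size=int(L), p=p)])
        out.append(ProteinRecord(f"{spec.name}|P{i+1:05d}", seq))
    return out


def gen_microbiome(
    spec: ProteomeSpec, seed: int, scale: float = 10.0, overlap: float = 0.7
) -> list[ProteinRecord]:
    """A ~``scale`` x larger reference with partially overlapping composition.

    The microbiome composition is a mixture: ``overlap`` of the paired
    proteome's composition plus ``1 - overlap`` of a deterministically
    permuted version, giving an overlapping but distinct pentamer population.
    """
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must be in [0, 1]")
    base = _composition_vector(spec.composition)
    perm = np.random.default_rng(seed + 1).permutation(20)
    mixed = overlap * base + (1.0 - overlap) * base[perm]
    micro_spec = ProteomeSpec(
        n_proteins=max(1, int(round(spec.n_proteins * scale))),
        min_length=spec.min_length,
        max_length=spec.max_length,
        composition={aa: float(mixed[i]) for i, aa in enumerate(AMINO_ACIDS)},
        name=spec.name + "-microbiome",
    )
    return gen_proteome(micro_spec, seed)


def gen_mutations(
    proteome: Sequence[ProteinRecord],
    n: int,
    seed: int,
    rare_bias: bool = False,
    case_id: str = "case1",
    margin: int = 14,
    rare_weight: float = 6.0,
) -> list[Mutation]:
    """``n`` interior missense mutations, verified against the proteome.

    Mutations are placed at least ``margin`` residues from both termini so
    every binding register of both widths exists.  Proteins are used one
    mutation each while they last, then recycled with distinct positions.
    With ``rare_bias`` the alternate residue is drawn preferentially from
    tryptophan, cysteine, histidine and methionine.
    """
    rng = np.random.default_rng(seed)
    eligible = [p for p in proteome if len(p) >= 2 * margin + 1]
    if not eligible:
        raise ValueError(f"no protein long enough for interior margin {margin}")
    capacity = sum(len(p) - 2 * margin for p in eligible)
    if n > capacity:
        raise ValueError(f"requested {n} mutations but only {capacity} interior positions")

    weights = np.ones(20)
    if rare_bias:
        for aa in RARE_RESIDUES:
            weights[AA_INDEX[aa]] = rare_weight

    # one mutation per protein while proteins last (round-robin over shuffles)
    order: list[int] = []
    while len(order) < n:
        idx = rng.permutation(len(eligible))
        order.extend(int(i) for i in idx)
    used: dict[int, set[int]] = {}
    out: list[Mutation] = []
    aas = list(AMINO_ACIDS)
    for pi in order:
        if len(out) == n:
            break
        protein = eligible[pi]
        lo, hi = margin + 1, len(protein) - margin
        taken = used.setdefault(pi, set())
        if len(taken) >= hi - lo + 1:
            continue
        while True:
            pos = int(rng.integers(lo, hi + 1))
            if pos not in taken:
                break
        taken.add(pos)
        ref = protein.sequence[pos - 1]
        w = weights.copy()
        w[AA_INDEX[ref]] = 0.0
        alt = aas[int(rng.choice(20, p=w / w.sum()))]
        out.append(Mutation(case_id, protein.protein_id, pos, ref, alt))
    return out


def gen_genotypes(
    n_cases: int,
    allele_pool: Optional[dict[str, Sequence[str]]] = None,
    homozygosity_rate: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Case genotypes: 6 class I slots (A1,A2,B1,B2,C1,C2) plus 2 DRB1 slots."""
    pool = DEFAULT_ALLELE_POOL if allele_pool is None else allele_pool
    for locus in ("A", "B", "C", "DRB1"):
        if locus not in pool or len(pool[locus]) < 1:
            raise ValueError(f"allele pool needs at least one {locus} allele")
    if not 0.0 <= homozygosity_rate <= 1.0:
        raise ValueError("homozygosity_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_cases):
        row = {"case_id": f"case{i+1:03d}"}
        for locus, slots in (("A", ("A1", "A2")), ("B", ("B1", "B2")),
                             ("C", ("C1", "C2")), ("DRB1", ("DRB1_1", "DRB1_2"))):
            alleles = list(pool[locus])
            first = alleles[int(rng.integers(len(alleles)))]
            if rng.random() < homozygosity_rate:
                second = first
            else:
                second = alleles[int(rng.integers(len(alleles)))]
            row[slots[0]], row[slots[1]] = first, second
        rows.append(row)
    return pd.DataFrame(rows, columns=["case_id", *GENOTYPE_COLUMNS])


@dataclass
class BindingTruth:
    """Ground-truth additive binding energy with anchor dominance.

    Ln(ic50) = intercept + sum over positions of weight[position, residue].
    Anchor pockets (p2/p9 for a 9mer; core p1,p4,p6,p9 = 15mer positions
    4,7,9,12 for a 15mer) carry ``anchor_factor`` x the non-anchor weight
    scale, so binding is dominated by the groove-facing residues.
    """

    allele: str
    width: int
    weights: np.ndarray  # (width, 20)
    intercept: float
    noise_sd: float
    anchor_factor: float

    def energy(self, peptides: Sequence[str]) -> np.ndarray:
        codes = np.array([[AA_INDEX[aa] for aa in p] for p in peptides])
        return self.weights[np.arange(self.width), codes].sum(axis=1)

    def ln_ic50(self, peptides: Sequence[str]) -> np.ndarray:
        return self.intercept + self.energy(peptides)

    # --- BindingPredictor interface: the noise-free truth as an oracle ---
    def predict_batch(self, peptides: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        mu = self.ln_ic50(peptides)
        return mu, np.zeros_like(mu)

    def predict(self, peptide: str) -> BindingPrediction:
        mu, sd = self.predict_batch([peptide])
        return BindingPrediction(self.allele, peptide, float(mu[0]), float(sd[0]))


ANCHOR_POSITIONS = {9: (2, 9), 15: (4, 7, 9, 12)}  # 1-based within the window


def gen_binding_truth(
    allele: str,
    seed: int,
    width: int = 9,
    anchor_factor: float = 5.0,
    base_sd: float = 0.20,
    noise_sd: float = 0.30,
    intercept: float = 8.5,  # exp(8.5) ~ 4900 nM mid-scale
    descriptor_dim: int = 3,
) -> BindingTruth:
    """Draw per-pocket residue weight vectors with anchor dominance.

    Pocket preferences are linear in the packaged physicochemical descriptor
    components (``descriptor_dim`` of them), so binding energy tracks residue
    chemistry rather than arbitrary residue labels; anchors are then scaled
    by ``anchor_factor``.
    """
    from .binding_model import compute_descriptors

    if anchor_factor < 1.0:
        raise ValueError("anchor dominance factor must be >= 1")
    if width not in (9, 15):
        raise ValueError("width must be 9 or 15")
    rng = np.random.default_rng(seed)
    scores = compute_descriptors(n_components=descriptor_dim).matrix()  # (20, d)
    coeff = rng.normal(0.0, base_sd, size=(width, descriptor_dim))
    weights = coeff @ scores.T  # (width, 20)
    for pos in ANCHOR_POSITIONS[width]:
        weights[pos - 1] *= anchor_factor
    weights -= weights.mean(axis=1, keepdims=True)
    return BindingTruth(allele, width, weights, intercept, noise_sd, anchor_factor)


def gen_random_peptides(
    n: int, width: int, seed: int, composition: Optional[dict[str, float]] = None
) -> list[str]:
    rng = np.random.default_rng(seed)
    p = _composition_vector(composition)
    aas = np.array(list(AMINO_ACIDS))
    return ["".join(aas[rng.choice(20, size=width, p=p)]) for _ in range(n)]


def gen_null_register_annotations(n_peptides: int, seed: int) -> pd.DataFrame:
    """Annotation-shaped records under register-uniform binding (the null).

    Each simulated mutant 9mer places the mutant in a uniformly random pocket
    and draws i.i.d. standard-normal Zscale scores for the six class I slots,
    so binding is independent of the register.  Under this null the expected
    exposure fraction is 5/9 ~ 0.55.
    """
    from .genotype_logic import CLASS_I_SLOTS
    from .motif_core import TCEM_I_POCKETS

    rng = np.random.default_rng(seed)
    pockets = rng.integers(1, 10, size=n_peptides)
    df = pd.DataFrame({
        "protein_id": "null", "position": np.arange(n_peptides) + 100,
        "alt_aa": "W", "width": 9, "pocket": pockets,
        "exposed": np.isin(pockets, TCEM_I_POCKETS),
    })
    for s in CLASS_I_SLOTS:
        df[f"z_mut_{s}"] = rng.normal(size=n_peptides)
    return df


def gen_training_set(
    truth: BindingTruth, n: int, seed: int, min_n: int = 200
) -> list[TrainingExample]:
    """Peptide/ic50 pairs: ic50 = exp(truth energy + Gaussian noise), in nM."""
    if n < min_n:
        raise ValueError(f"training sets require n >= {min_n}, got {n}")
    rng = np.random.default_rng(seed)
    peptides = gen_random_peptides(n, truth.width, seed + 1)
    ln = truth.ln_ic50(peptides) + rng.normal(0.0, truth.noise_sd, size=n)
    return [
        TrainingExample(truth.allele, p, float(np.exp(v)))
        for p, v in zip(peptides, ln)
    ]
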