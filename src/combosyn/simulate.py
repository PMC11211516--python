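"""Synthetic benchmark generator with a planted synergy signal.

Emits the three tables the pipeline reads — an expression matrix, a drug →
SMILES table drawn from a packaged library of drug-like molecules, and a
combination table with four correlated synergy scores — with known ground
truth, so every stage and the end-to-end training loop are testable without
any external download.

The planted signal: each cell line gets a latent vector ``u_c`` (a fixed
random projection of its expression profile) and each drug a latent
``t_d`` (a fixed projection of a 64-bin hashed substructure-count
fingerprint, deliberately independent of the learned graph encoder). The
latent synergy of a triple is the symmetric form

    s_raw = t_A · t_B + u_c · (t_A + t_B)

(drug × drug and cell × drug interactions) standardized over the
generated triples, scaled by
``effect_size`` and perturbed with Gaussian noise. Because part of every
drug panel consists of skeletal-isomer families whose mean atom-feature
summaries coincide exactly, a slice of the planted drug signal is carried
by per-atom structure that composition averages cannot see. The four reported scores are the latent
score under independent multiplicative (sign-preserving) jitter, except
for a ``discordant_frac`` fraction of records where one randomly chosen
score's sign is flipped — those records exercise the consensus-exclusion
rule downstream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from rdkit import Chem

from .data import SCORE_NAMES

__all__ = [
    "SimConfig",
    "SMILES_LIBRARY",
    "substructure_fingerprint",
    "simulate_expression",
    "simulate_drugs",
    "simulate_synergy_triples",
    "simulate_tables",
]

#: Skeletal-isomer families (same molecular formula, same heavy-bond count,
#: different branching or heteroatom placement). Members of one family have
#: *exactly equal column means* of the 9-column atom-feature matrix — equal
#: element, degree, H-count, hybridization, aromaticity and ring averages —
#: so any mean-pooled composition summary collapses the family, while the
#: per-atom feature rows (and the graph topology) differ, letting a graph
#: encoder resolve it. Part of every simulated drug panel is drawn from
#: these families.
ISOMER_FAMILIES: tuple[tuple[str, str, str], ...] = (
    ("CCCCc1ccccc1", "CC(C)Cc1ccccc1", "CC(C)(C)c1ccccc1"),
    ("CCCCCO", "CC(C)CCO", "CCC(C)CO"),
    ("CCCCO", "CCOCC", "CC(C)CO"),
    ("CCCCCC", "CC(C)CCC", "CC(C)(C)CC"),
    ("CCCCN", "CCNCC", "CC(C)(C)N"),
    ("CCCCCl", "CC(C)CCl", "CC(C)(C)Cl"),
    ("CC(=O)CCC", "CCC(=O)CC", "CC(=O)C(C)C"),
    ("CCC(=O)O", "CC(=O)OC", "O=COCC"),
    ("CCCC(=O)O", "CCOC(C)=O", "CCC(=O)OC"),
    ("CCCCC", "CC(C)CC", "CC(C)(C)C"),
    ("CCCCCCl", "CC(C)CCCl", "CCC(C)(C)Cl"),
    ("CCCCC=O", "CC(C)CC=O", "CCC(C)C=O"),
    ("CCCCS", "CC(C)CS", "CCSCC"),
    ("CCCCCN", "CC(C)CCN", "CCNCCC"),
    ("CCCCC#N", "CC(C)CC#N", "CCC(C)C#N"),
)

#: Packaged library of valid drug-like SMILES (well-known small molecules
#: plus systematically substituted scaffolds). All entries parse.
DIVERSE_SMILES: tuple[str, ...] = (
    "CC(=O)Oc1ccccc1C(=O)O",            # aspirin
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",       # caffeine
    "CC(=O)Nc1ccc(O)cc1",               # paracetamol
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",       # ibuprofen
    "COc1ccc2cc(ccc2c1)C(C)C(=O)O",     # naproxen
    "CN1CCC[C@H]1c1cccnc1",             # nicotine
    "NC(=O)c1ccc[nH]1",
    "OC(=O)c1ccccc1O",                  # salicylic acid
    "Nc1ccc(cc1)S(N)(=O)=O",            # sulfanilamide
    "CC(N)Cc1ccccc1",                   # amphetamine
    "CN(C)CCc1c[nH]c2ccccc12",          # DMT
    "OCC(O)CO",                         # glycerol
    "CC(=O)NCCc1c[nH]c2ccc(OC)cc12",    # melatonin
    "NC(Cc1ccc(O)cc1)C(=O)O",           # tyrosine
    "NC(Cc1c[nH]c2ccccc12)C(=O)O",      # tryptophan
    "OC(=O)CCc1ccccc1",
    "COc1cc2c(cc1OC)CCN(C)CC2",
    "CCN(CC)CCNC(=O)c1ccc(N)cc1",       # procainamide
    "CC(C)NCC(O)c1ccc(O)c(O)c1",        # isoprenaline
    "CNCC(O)c1ccc(O)c(O)c1",            # adrenaline
    "NCCc1ccc(O)c(O)c1",                # dopamine
    "NCCc1c[nH]cn1",                    # histamine
    "OC(=O)c1cc(O)c(O)c(O)c1",          # gallic acid
    "Oc1ccc(cc1)C=Cc1cc(O)cc(O)c1",     # resveratrol
    "COc1ccccc1OCCNCC(O)COc1ccccc1",
    "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1",    # salbutamol
    "CC(C)(C)NCC(O)COc1cccc2ccccc12",   # propranolol
    "CCOC(=O)c1ccccc1N",
    "Cc1ccc(cc1)S(=O)(=O)N",
    "Nc1ncnc2[nH]cnc12",                # adenine
    "Nc1nc2[nH]cnc2c(=O)[nH]1",         # guanine
    "Cc1c[nH]c(=O)[nH]c1=O",            # thymine
    "Nc1cc[nH]c(=O)n1",                 # cytosine
    "O=c1cc[nH]c(=O)[nH]1",             # uracil
    "OC(=O)c1ccncc1",                   # isonicotinic acid
    "NNC(=O)c1ccncc1",                  # isoniazid
    "OCCN1CCN(CCCN2c3ccccc3Sc3ccc(Cl)cc23)CC1",  # perphenazine-like
    "CN1CCN(CC1)c1ccccc1",
    "Clc1ccc2nc(N3CCNCC3)c(nc2c1)-c1ccccc1",
    "CC(=O)c1ccc(cc1)S(=O)(=O)N",
    "COc1ccc(CCN)cc1",
    "Cn1cc(c2ccccc12)C(=O)O",
    "OC(=O)Cc1ccccc1Nc1c(Cl)cccc1Cl",   # diclofenac
    "CC(C(=O)O)c1ccc(cc1)C(=O)c1ccccc1",  # ketoprofen
    "OC(=O)c1ccc(cc1)NC(=O)c1ccccc1",
    "CN(C)c1ccc(cc1)C(=O)O",
    "CSCCC(N)C(=O)O",                   # methionine
    "NC(CS)C(=O)O",                     # cysteine
    "NC(CCC(=O)O)C(=O)O",               # glutamate
    "OC(=O)C1CCCN1",                    # proline
    "NC(Cc1ccccc1)C(=O)O",              # phenylalanine
    "CC(O)C(N)C(=O)O",                  # threonine
    "CC(C)C(N)C(=O)O",                  # valine
    "OCC1OC(O)C(O)C(O)C1O",             # glucose
    "Cc1cccc(C)c1C",
    "COc1ccc(cc1)C(=O)O",
    "CCOc1ccc(cc1)C(=O)O",
    "Fc1ccc(cc1)C(=O)O",
    "Clc1ccc(cc1)C(=O)O",
    "Brc1ccc(cc1)C(=O)O",
    "Ic1ccc(cc1)C(=O)O",
    "Oc1ccc(cc1)C(=O)O",
    "Nc1ccc(cc1)C(=O)O",
    "OC(=O)c1ccc(cc1)C#N",
    "OC(=O)c1ccc(cc1)[N+]([O-])=O",
    "CC(C)(C)c1ccc(O)cc1",
    "Oc1ccc(Cl)cc1Cl",
    "Oc1ccc(cc1)-c1ccccc1",
    "c1ccc2[nH]ccc2c1",                 # indole
    "c1ccc2occc2c1",                    # benzofuran
    "c1ccc2sccc2c1",                    # benzothiophene
    "c1ccc2ncccc2c1",                   # quinoline
    "c1ccc2cnccc2c1",                   # isoquinoline
    "c1cnc2[nH]ccc2c1",
    "c1ccn2ccnc2c1",
    "Cn1ccnc1",                         # N-methylimidazole
    "c1cscn1",                          # thiazole
    "c1conc1",                          # isoxazole
    "c1cnoc1",
    "C1CCNCC1",                         # piperidine
    "C1CNCCN1",                         # piperazine
    "C1CCOC1",                          # THF
    "C1CCNC1",                          # pyrrolidine
    "O=C1CCCCC1",                       # cyclohexanone
    "OC1CCCCC1",                        # cyclohexanol
    "NC1CCCCC1",
    "C1CC1c1ccccc1",
    "CC1(C)CCCC1",
    "CC(=O)N1CCCC1",
    "O=C(Nc1ccccc1)c1ccccc1",           # benzanilide
    "O=C(Oc1ccccc1)c1ccccc1",
    "CN(C)C(=O)c1ccccc1",
    "CCOC(=O)CC(=O)OCC",                # diethyl malonate
    "CC(=O)CC(=O)C",                    # acetylacetone
    "CCCCCCCC(=O)O",                    # octanoic acid
    "CCCCCC=CCC=CCCCCCCCC(=O)O",        # linoleic-like
    "OCCOCCO",
    "NCCO",                             # ethanolamine
    "NCCCCN",                           # putrescine
    "NCCCCCN",                          # cadaverine
    "OC(=O)CCC(=O)O",                   # succinic acid
    "OC(=O)C=CC(=O)O",                  # fumaric acid
    "OC(=O)C(O)C(O)C(=O)O",             # tartaric acid
    "OC(=O)CC(O)(CC(=O)O)C(=O)O",       # citric acid
    "CC(O)C(=O)O",                      # lactic acid
    "CC(=O)OCC(COC(C)=O)OC(C)=O",       # triacetin
    "Cc1ncc([N+]([O-])=O)n1CCO",        # metronidazole
    "OCC1OC(C(O)C1O)n1cnc2c(N)ncnc12",  # adenosine
    "CC1CC(C)C(=O)C(C1)C(O)CC1CC(=O)NC(=O)C1",  # cycloheximide
    "CN1C2CCC1CC(C2)OC(=O)C(CO)c1ccccc1",  # atropine
    "COC(=O)C1C2CCC(CC1OC(=O)c1ccccc1)N2C",  # cocaine
    "CN1CCC23c4c5ccc(O)c4OC2C(O)C=CC3C1C5",  # morphine
    "CCN(CC)C(=O)C1CN(C)C2Cc3c[nH]c4cccc(C2=C1)c34",  # LSD-like ergoline
    "Clc1ccccc1-c1nc2ccccc2[nH]1",
    "Fc1ccc(cc1)C(=O)CCCN1CCC(O)(CC1)c1ccc(Cl)cc1",  # haloperidol
    "CC(N)Cc1ccc2OCOc2c1",              # MDA
    "COc1cc(CC=C)ccc1O",                # eugenol
    "COc1ccc(C=CC(=O)O)cc1O",           # ferulic acid
    "CC(C)=CCc1c(O)cc(O)c2c1oc(cc2=O)-c1ccccc1",  # prenyl-flavone
)

#: full library: all isomer-family members followed by the diverse set
SMILES_LIBRARY: tuple[str, ...] = tuple(
    s for fam in ISOMER_FAMILIES for s in fam
) + DIVERSE_SMILES


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic benchmark.

    Defaults are the desk-scale benchmark: 20 cell lines × 30 drugs,
    600 combination triples over 496 landmark genes.
    """

    n_cells: int = 20
    n_drugs: int = 30
    n_triples: int = 600
    gene_dim: int = 496
    effect_size: float = 2.5
    noise_sd: float = 0.5
    discordant_frac: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if min(self.n_cells, self.n_drugs, self.n_triples, self.gene_dim) < 1:
            raise ValueError("all counts must be >= 1")
        if self.gene_dim % 2 != 0:
            raise ValueError("gene_dim must be even (the vector is split into halves)")
        if not 0.0 <= self.discordant_frac <= 1.0:
            raise ValueError("discordant_frac must be a probability")
        if self.n_drugs > len(SMILES_LIBRARY):
            raise ValueError(
                f"n_drugs={self.n_drugs} exceeds the packaged SMILES library "
                f"({len(SMILES_LIBRARY)} molecules)"
            )

    def easy(self) -> "SimConfig":
        """Strong-effect, low-noise variant of these conditions."""
        return replace(self, effect_size=4.0, noise_sd=0.25, discordant_frac=0.05)


#: latent dimensionality of the planted cell/drug factors
_LATENT_DIM = 8
#: fixed seed for the projection matrices defining the planted signal;
#: a constant of the generator's definition, not a tunable
_PROJECTION_SEED = 20240614
#: sd of the per-score multiplicative (sign-preserving) jitter
_SCORE_JITTER_SD = 0.15
#: synergy-score scale factor (puts scores in the usual ±tens range)
_SCORE_SCALE = 10.0
#: weight of the standardized (family-resolving) fingerprint component in
#: the drug latent; the raw-count component carries the bulk of the signal
_FAMILY_COMPONENT_WEIGHT = 0.35


def substructure_fingerprint(smiles: str, n_bits: int = 64) -> np.ndarray:
    """64-bin hashed substructure-count fingerprint.

    Counts atom environments (element, degree, aromaticity), bond
    environments (sorted endpoint elements + ring/aromatic flags) and
    length-2 path environments (canonically oriented atom triples), hashed
    with CRC-32 into ``n_bits`` bins. The path features are what separate
    positional isomers — substitution patterns that share every atom and
    bond environment still differ in their triples. Stable across runs and
    independent of the learned graph encoder, so the planted signal cannot
    leak the model's own representation.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    if n_bits % 2 != 0:
        raise ValueError("n_bits must be even (half composition, half path bins)")
    half = n_bits // 2
    fp = np.zeros(n_bits, dtype=np.float64)

    def bump(key: str, offset: int):
        fp[offset + zlib.crc32(key.encode()) % half] += 1.0

    def tag(atom) -> str:
        return f"{atom.GetAtomicNum()}.{int(atom.GetIsAromatic())}.{atom.GetTotalNumHs()}"

    # composition bins (first half): atom and bond environments
    for atom in mol.GetAtoms():
        bump(f"A:{atom.GetAtomicNum()}:{atom.GetDegree()}:{int(atom.GetIsAromatic())}", 0)
    for bond in mol.GetBonds():
        z = sorted((bond.GetBeginAtom().GetAtomicNum(), bond.GetEndAtom().GetAtomicNum()))
        bump(f"B:{z[0]}:{z[1]}:{int(bond.GetIsAromatic())}:{int(bond.IsInRing())}", 0)
    # topology bins (second half): length-2 path environments
    for center in mol.GetAtoms():
        nbrs = list(center.GetNeighbors())
        for i in range(len(nbrs)):
            for j in range(i + 1, len(nbrs)):
                ends = sorted((tag(nbrs[i]), tag(nbrs[j])))
                bump(f"P:{ends[0]}:{tag(center)}:{ends[1]}", half)
    return fp


def simulate_expression(cfg: SimConfig) -> pd.DataFrame:
    """Cell-line × gene expression table from per-cell Gaussian mixtures.

    Each cell line owns three 2-D mixture centers; every (first-half,
    second-half) gene pair draws its mean from one of them, so the paired
    point cloud — hence the density map — is a cell-specific blob pattern.
    """
    rng = np.random.default_rng(cfg.seed)
    half = cfg.gene_dim // 2
    rows = []
    ids = [f"CL{i:03d}" for i in range(cfg.n_cells)]
    for _ in ids:
        centers = rng.uniform(-3.0, 3.0, size=(3, 2))
        weights = rng.dirichlet(np.ones(3))
        comp = rng.choice(3, size=half, p=weights)
        means = centers[comp]  # (half, 2)
        jitter = rng.normal(0.0, 0.4, size=(half, 2))
        pair_vals = means + jitter
        rows.append(np.concatenate([pair_vals[:, 0], pair_vals[:, 1]]))
    df = pd.DataFrame(np.array(rows), index=pd.Index(ids, name="cell_line_id"))
    df.columns = [f"g{j:04d}" for j in range(cfg.gene_dim)]
    return df


def simulate_drugs(cfg: SimConfig) -> pd.DataFrame:
    """Seeded drug panel from the packaged SMILES library.

    A fixed share of the panel is filled with complete skeletal-isomer
    families, the rest with structurally diverse singletons. The families
    guarantee that part of the planted drug signal is invisible to
    mean-pooled composition summaries (their column-mean atom features
    coincide exactly), mirroring how real panels contain close analogues
    that composition summaries cannot tell apart.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n_families = min(cfg.n_drugs // 4, len(ISOMER_FAMILIES))
    fam_idx = rng.choice(len(ISOMER_FAMILIES), size=n_families, replace=False)
    smiles = [s for i in fam_idx for s in ISOMER_FAMILIES[i]]
    fam_set = {s for fam in ISOMER_FAMILIES for s in fam}
    singles_pool = [s for s in SMILES_LIBRARY if s not in fam_set]
    n_singles = cfg.n_drugs - len(smiles)
    if n_singles > 0:
        single_idx = rng.choice(len(singles_pool), size=n_singles, replace=False)
        smiles += [singles_pool[i] for i in single_idx]
    smiles = smiles[: cfg.n_drugs]
    return pd.DataFrame(
        {"smiles": smiles},
        index=pd.Index([f"D{i:03d}" for i in range(cfg.n_drugs)], name="drug_id"),
    )


def _cell_latents(expression: pd.DataFrame) -> dict[str, np.ndarray]:
    proj_rng = np.random.default_rng(_PROJECTION_SEED)
    P = proj_rng.normal(size=(expression.shape[1], _LATENT_DIM))
    out = {}
    for cid, row in zip(expression.index, expression.to_numpy(dtype=np.float64)):
        v = row @ P / np.sqrt(expression.shape[1])
        out[cid] = v / np.linalg.norm(v)
    return out


def _drug_latents(drugs: pd.DataFrame) -> dict[str, np.ndarray]:
    """Unit-norm drug latents from the hashed fingerprints.

    Two components are blended before normalization: a projection of the
    raw counts (dominated by overall size and composition — smooth,
    readily learnable structure) and a smaller projection of the
    panel-standardized, clipped bin z-scores (which resolve fine
    structural differences, including the skeletal-isomer families whose
    composition means coincide). Composition-blind drug summaries lose
    exactly the second component's within-family share.
    """
    proj_rng = np.random.default_rng(_PROJECTION_SEED + 1)
    P_raw = proj_rng.normal(size=(64, _LATENT_DIM))
    P_fine = proj_rng.normal(size=(64, _LATENT_DIM))
    F = np.stack([substructure_fingerprint(s) for s in drugs["smiles"]])
    sd = F.std(axis=0)
    Z = np.clip((F - F.mean(axis=0)) / np.where(sd > 0, sd, np.inf), -3.0, 3.0)
    V = F @ P_raw / 8.0
    VZ = Z @ P_fine / 8.0
    V /= max(np.mean(np.linalg.norm(V, axis=1)), 1e-12)
    VZ /= max(np.mean(np.linalg.norm(VZ, axis=1)), 1e-12)
    T = V + _FAMILY_COMPONENT_WEIGHT * VZ
    out = {}
    for did, v in zip(drugs.index, T):
        nrm = np.linalg.norm(v)
        out[did] = v / (nrm if nrm > 0 else 1.0)
    return out


def simulate_synergy_triples(
    cfg: SimConfig, expression: pd.DataFrame, drugs: pd.DataFrame
) -> pd.DataFrame:
    """Combination table with four correlated scores and planted signal."""
    if expression.empty or drugs.empty:
        raise ValueError("expression and drug tables must be nonempty")
    rng = np.random.default_rng(cfg.seed + 2)
    cells = list(expression.index)
    drug_ids = sorted(drugs.index)
    pairs = [
        (drug_ids[i], drug_ids[j])
        for i in range(len(drug_ids))
        for j in range(i + 1, len(drug_ids))
    ]
    all_triples = [(a, b, c) for (a, b) in pairs for c in cells]
    if cfg.n_triples > len(all_triples):
        raise ValueError(
            f"n_triples={cfg.n_triples} exceeds the {len(all_triples)} distinct triples"
        )
    chosen = rng.choice(len(all_triples), size=cfg.n_triples, replace=False)
    triples = [all_triples[i] for i in chosen]

    u = _cell_latents(expression)
    t = _drug_latents(drugs)
    raw = np.array(
        [t[a] @ t[b] + u[c] @ (t[a] + t[b]) for (a, b, c) in triples]
    )
    raw = (raw - np.median(raw)) / (raw.std() + 1e-12)
    s = cfg.effect_size * raw + rng.normal(0.0, cfg.noise_sd, size=len(raw))

    jitter = np.exp(rng.normal(0.0, _SCORE_JITTER_SD, size=(len(s), 4)))
    scores = _SCORE_SCALE * s[:, None] * jitter  # sign-consistent quadruples
    flip = rng.random(len(s)) < cfg.discordant_frac
    which = rng.integers(0, 4, size=len(s))
    scores[flip, which[flip]] *= -1.0

    df = pd.DataFrame(triples, columns=["drug_a", "drug_b", "cell_line"])
    for k, name in enumerate(SCORE_NAMES):
        df[name] = scores[:, k]
    return df


def simulate_tables(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate all three tables under one config."""
    expression = simulate_expression(cfg)
    drugs = simulate_drugs(cfg)
    combos = simulate_synergy_triples(cfg, expression, drugs)
    return expression, drugs, combos
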