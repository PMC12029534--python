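"""Synthetic paired tumor/adjacent metabolomics cohorts with planted structure.

The generator emulates the statistical shape of an LC-MS tissue cohort:
log-normal metabolite intensities, paired tumor and adjacent samples per
patient with TNM stage labels, planted tumor-vs-adjacent log2 fold changes,
stage-wise rank-correlation structure with monotone trajectories, spiked
internal standards and tissue-weight nuisance factors, and pooled-QC
replicate injections at a target RSD.  Everything planted is recorded in a
GroundTruth object so recovery tests can score the analysis end to end.

Rank correlations are planted through a Gaussian copula: a target Spearman
rho_s is realized by drawing latent normals with Pearson parameter
r = 2·sin(pi·rho_s/6), the exact population inverse of the bivariate-normal
Spearman relation rho_s = (6/pi)·asin(r/2).  Targets are therefore stated on
the same (Spearman) scale the analysis consumes, with no calibration loop.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import MetaboliteRecord, PeakTable, SampleRecord

DEFAULT_STAGE_COUNTS = {"I": 13, "II": 24, "III": 39, "IV": 4}
DEFAULT_CLASS_PROPORTIONS = {
    "FFA": 0.17,
    "carnitine": 0.09,
    "OH-carnitine": 0.03,
    "PC": 0.15,
    "LPC": 0.09,
    "SM": 0.06,
    "amino_acid": 0.21,
    "nucleoside": 0.05,
    "other": 0.15,
}

IS_POS = "IS_carnitine_C2_d3"
IS_NEG = "IS_FFA_C16_d4"


@dataclass
class PlantedEdge:
    """A metabolite pair with per-stage target Spearman correlations in tumor tissue."""

    pair: tuple[str, str]
    rho_by_stage: tuple[float, float, float]
    rho_adjacent: float = 0.0

    def __post_init__(self) -> None:
        for r in (*self.rho_by_stage, self.rho_adjacent):
            if not -1 < r < 1:
                raise ValueError(f"planted rho must lie in (-1, 1), got {r}")

    @property
    def monotone(self) -> bool:
        w = self.rho_by_stage
        return (w[0] <= w[1] <= w[2]) or (w[0] >= w[1] >= w[2])


@dataclass
class SyntheticConfig:
    n_patients: int = 80
    stage_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_COUNTS))
    n_metabolites: int = 234
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS))
    effect_table: list[tuple[str, float]] | None = None  # (metabolite_id, log2FC)
    effect_fraction: float = 0.3      # used when effect_table is None
    effect_log2fc_range: tuple[float, float] = (0.5, 2.0)
    corr_blocks: list[PlantedEdge] | None = None          # None → default structure
    clinical_indices: dict[str, list[str]] = field(default_factory=lambda: {
        "lauren": ["intestinal", "mixed", "diffuse"],
        "nerve_invasion": ["no", "yes"],
        "vascular_invasion": ["no", "yes"],
    })
    qc_target_rsd: float = 15.0       # %
    qc_every: int = 10                # one pooled-QC injection per 10 samples
    noise_sd: float = 0.4             # natural-log scale biological+technical spread
    is_nuisance_sd: float = 0.1       # per-sample internal-standard response spread
    weight_range: tuple[float, float] = (10.0, 50.0)  # mg
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.stage_counts.values()) != self.n_patients:
            raise ValueError(
                f"stage_counts sum {sum(self.stage_counts.values())} "
                f"!= n_patients {self.n_patients}")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"class_proportions sum to {total}, expected 1")


@dataclass
class GroundTruth:
    differential: dict[str, float]           # metabolite_id -> planted log2FC
    planted_edges: list[PlantedEdge]
    monotone_edges: list[tuple[str, str]]    # pairs whose trajectory is monotone
    planted_hub: str | None
    latent_log: pd.DataFrame                 # samples × metabolites, pre-noise-free scale

    def to_json(self, path) -> None:
        payload = {
            "differential": self.differential,
            "planted_edges": [
                {"pair": list(e.pair), "rho_by_stage": list(e.rho_by_stage),
                 "rho_adjacent": e.rho_adjacent}
                for e in self.planted_edges
            ],
            "monotone_edges": [list(p) for p in self.monotone_edges],
            "planted_hub": self.planted_hub,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# Copula mapping
# ---------------------------------------------------------------------------


def rank_target_copula(rho_target: float) -> float:
    """Pearson parameter of the Gaussian copula yielding Spearman ``rho_target``."""
    if not -1 < rho_target < 1:
        raise ValueError(f"|rho_target| must be < 1, got {rho_target}")
    return 2.0 * math.sin(math.pi * rho_target / 6.0)


# ---------------------------------------------------------------------------
# Metabolite catalog
# ---------------------------------------------------------------------------

_CARNITINES = [
    "carnitine_C0", "carnitine_C2", "carnitine_C3", "carnitine_C4",
    "carnitine_C5", "carnitine_C6", "carnitine_C8", "carnitine_C10",
    "carnitine_C12", "carnitine_C14", "carnitine_C14:1", "carnitine_C16",
    "carnitine_C16:1", "carnitine_C18", "carnitine_C18:1", "carnitine_C18:2",
]
_OH_CARNITINES = ["carnitine_C4-OH", "carnitine_C6-OH", "carnitine_C8-OH",
                  "carnitine_C10-OH", "carnitine_C16-OH"]
_AMINO_ACIDS = [
    "glycine", "alanine", "serine", "proline", "valine", "threonine",
    "leucine", "isoleucine", "aspartate", "glutamate", "glutamine",
    "methionine", "phenylalanine", "tyrosine", "tryptophan", "lysine",
    "arginine", "histidine",
]
_OTHERS = ["choline", "glycerophosphorylcholine", "acetylcholine",
           "creatine", "taurine", "hypotaurine", "carnosine"]
_NUCLEOSIDES = ["adenosine", "guanosine", "cytidine", "uridine", "inosine"]


def default_metabolite_catalog(n_metabolites: int,
                               class_proportions: dict[str, float]
                               ) -> list[MetaboliteRecord]:
    """A plausible annotation catalog of ``n_metabolites`` analytes plus 2 standards.

    A fixed core (the acylcarnitine panel, key fatty acids, choline species,
    amino acids) is always present so ratio-panel and hub analyses resolve;
    the remainder is filled per chemical-class proportions with systematic
    lipid names.  FFAs are assigned the negative-mode internal standard,
    everything else the positive-mode one.
    """
    core: list[tuple[str, str]] = []
    core += [(m, "carnitine") for m in _CARNITINES]
    core += [(m, "OH-carnitine") for m in _OH_CARNITINES]
    core += [(f"FFA_C{c}_{d}", "FFA")
             for c, d in [(15, 0), (16, 0), (16, 1), (17, 1), (18, 1), (18, 2),
                          (18, 3), (20, 1), (20, 2), (20, 3), (20, 4), (22, 3),
                          (22, 4), (22, 6)]]
    core += [("PC_30_0", "PC"), ("PC_32_1", "PC"), ("PC_33_1", "PC"),
             ("PC_34_2", "PC"), ("PC_36_4", "PC")]
    core += [("LPC_14_0", "LPC"), ("LPC_16_0", "LPC"), ("LPC_18_1", "LPC")]
    core += [("SM_34_0", "SM"), ("SM_34_1", "SM")]
    core += [(m, "amino_acid") for m in _AMINO_ACIDS]
    core += [(m, "other") for m in _OTHERS]
    core += [(m, "nucleoside") for m in _NUCLEOSIDES]
    if n_metabolites < 30:
        # small test cohorts: keep the ratio-panel core, then truncate
        core = core[: n_metabolites]

    counts = {cls: int(round(frac * n_metabolites))
              for cls, frac in class_proportions.items()}
    have: dict[str, int] = {}
    for _, cls in core:
        have[cls] = have.get(cls, 0) + 1
    fillers = {
        "FFA": lambda i: f"FFA_C{14 + i % 12}_{i % 6}x{i}",
        "carnitine": lambda i: f"carnitine_C{20 + i}",
        "OH-carnitine": lambda i: f"carnitine_C{12 + 2 * i}-OH",
        "PC": lambda i: f"PC_{30 + i % 12}_{i % 6}x{i}",
        "LPC": lambda i: f"LPC_{14 + i % 10}_{i % 4}x{i}",
        "SM": lambda i: f"SM_{32 + i % 10}_{i % 3}x{i}",
        "amino_acid": lambda i: f"aa_derivative_{i}",
        "nucleoside": lambda i: f"nucleoside_{i}",
        "other": lambda i: f"metabolite_x{i}",
    }
    records = [MetaboliteRecord(mid, chemical_class=cls,
                                internal_standard_id=IS_NEG if cls == "FFA" else IS_POS,
                                ionization_mode="ESI-" if cls == "FFA" else "ESI+")
               for mid, cls in core]
    seen = {r.metabolite_id for r in records}
    i = 0

    def fresh(cls: str) -> str:
        nonlocal i
        while True:
            mid = fillers[cls](i)
            i += 1
            if mid not in seen:
                seen.add(mid)
                return mid

    while len(records) < n_metabolites:
        # round-robin over classes still below their quota
        progressed = False
        for cls in class_proportions:
            if len(records) >= n_metabolites:
                break
            if have.get(cls, 0) < counts.get(cls, 0):
                records.append(MetaboliteRecord(
                    fresh(cls), chemical_class=cls,
                    internal_standard_id=IS_NEG if cls == "FFA" else IS_POS,
                    ionization_mode="ESI-" if cls == "FFA" else "ESI+"))
                have[cls] = have.get(cls, 0) + 1
                progressed = True
        if not progressed:
            records.append(MetaboliteRecord(fresh("other"), chemical_class="other",
                                            internal_standard_id=IS_POS))
    records = records[: n_metabolites]
    # spiked standards, self-assigned (normalization drops them from analytes)
    records.append(MetaboliteRecord(IS_POS, chemical_class="other",
                                    internal_standard_id=IS_POS,
                                    ionization_mode="ESI+"))
    records.append(MetaboliteRecord(IS_NEG, chemical_class="other",
                                    internal_standard_id=IS_NEG,
                                    ionization_mode="ESI-"))
    return records


def default_planted_edges(metabolite_ids: list[str]) -> list[PlantedEdge]:
    """Default planted structure: decreasing fatty-acid pairs + a growing hub star.

    Eight disjoint FFA pairs lose correlation with progression (0.8→0.5→0.1),
    mirroring dissolving lipid co-regulation; a hydroxybutyrylcarnitine hub
    gains partners stage by stage at a modest rho kept inside the
    positive-definiteness budget of a star (sum of squared Pearson r < 1).
    """
    ffas = [m for m in metabolite_ids if m.startswith("FFA_")]
    edges: list[PlantedEdge] = []
    for i in range(0, min(16, len(ffas) - 1), 2):
        edges.append(PlantedEdge((ffas[i], ffas[i + 1]), (0.8, 0.5, 0.1)))
    hub = "carnitine_C4-OH"
    partners = [m for m in metabolite_ids
                if m.startswith("carnitine_") and m not in (hub,)][:6]
    if hub in metabolite_ids and len(partners) == 6:
        for k, p in enumerate(partners):
            if k < 2:
                rho = (0.35, 0.35, 0.35)
            elif k < 4:
                rho = (0.0, 0.35, 0.35)
            else:
                rho = (0.0, 0.0, 0.35)
            edges.append(PlantedEdge((hub, p), rho))
    return edges


# ---------------------------------------------------------------------------
# Correlation assembly
# ---------------------------------------------------------------------------


def _correlation_matrix(metabolite_ids: list[str], pairs: list[tuple[str, str, float]],
                        ) -> np.ndarray:
    """Identity plus planted Pearson entries; Cholesky-validated."""
    index = {m: i for i, m in enumerate(metabolite_ids)}
    R = np.eye(len(metabolite_ids))
    touched = set()
    for a, b, rho_s in pairs:
        if rho_s == 0:
            continue
        i, j = index[a], index[b]
        r = rank_target_copula(rho_s)
        R[i, j] = R[j, i] = r
        touched.update((i, j))
    if touched:
        idx = sorted(touched)
        sub = R[np.ix_(idx, idx)]
        try:
            np.linalg.cholesky(sub)
        except np.linalg.LinAlgError:
            names = [metabolite_ids[i] for i in idx]
            raise ValueError(
                f"planted correlation block is not positive definite: {names}"
            ) from None
    return R


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(cfg: SyntheticConfig) -> tuple[
        PeakTable, list[SampleRecord], list[MetaboliteRecord], GroundTruth]:
    """Generate a raw peak table, metadata, annotations and ground truth.

    Latent log-intensities are drawn per sample group (tumor samples of each
    TNM stage; all adjacent samples) from a multivariate normal realizing the
    planted Spearman structure, shifted by the planted effects in tumor
    samples, exponentiated, and multiplied by per-sample internal-standard
    and tissue-weight nuisance factors.  Pooled-QC injections replicate the
    pooled tissue mean with log-normal noise solved from the target RSD.
    The same seed reproduces the output bit for bit.
    """
    rng = np.random.default_rng(cfg.seed)
    mets = default_metabolite_catalog(cfg.n_metabolites, cfg.class_proportions)
    analyte_ids = [m.metabolite_id for m in mets
                   if m.internal_standard_id != m.metabolite_id]
    is_ids = [m.metabolite_id for m in mets
              if m.internal_standard_id == m.metabolite_id]
    m = len(analyte_ids)

    # --- patients, stages, clinical indices --------------------------------
    stages_per_patient: list[str] = []
    for stage, count in cfg.stage_counts.items():
        stages_per_patient += [stage] * count
    order = rng.permutation(cfg.n_patients)
    stages_per_patient = [stages_per_patient[i] for i in order]

    samples: list[SampleRecord] = []
    for i, stage in enumerate(stages_per_patient):
        pid = f"P{i + 1:03d}"
        weight_t = float(rng.uniform(*cfg.weight_range))
        weight_a = float(rng.uniform(*cfg.weight_range))
        clinical = {name: str(rng.choice(levels))
                    for name, levels in cfg.clinical_indices.items()}
        samples.append(SampleRecord(f"{pid}_T", pid, "tumor", weight_t, stage, clinical))
        samples.append(SampleRecord(f"{pid}_A", pid, "adjacent", weight_a, stage,
                                    dict(clinical)))

    # --- planted effects ---------------------------------------------------
    if cfg.effect_table is None:
        n_eff = int(round(cfg.effect_fraction * m))
        chosen = rng.choice(m, size=n_eff, replace=False)
        lo, hi = cfg.effect_log2fc_range
        effects = {
            analyte_ids[j]: float(rng.uniform(lo, hi) * rng.choice([-1.0, 1.0]))
            for j in chosen
        }
    else:
        effects = {mid: float(fc) for mid, fc in cfg.effect_table}
        unknown = set(effects) - set(analyte_ids)
        if unknown:
            raise ValueError(f"effect_table references unknown metabolites: {sorted(unknown)}")

    # --- planted correlation structure -------------------------------------
    edges = cfg.corr_blocks
    if edges is None:
        edges = default_planted_edges(analyte_ids)
    for e in edges:
        for mid in e.pair:
            if mid not in analyte_ids:
                raise ValueError(f"planted edge references unknown metabolite {mid!r}")
    stage_labels = ("I", "II", "III")
    chol: dict[str, np.ndarray | None] = {}
    for k, t in enumerate(stage_labels):
        pairs = [(e.pair[0], e.pair[1], e.rho_by_stage[k]) for e in edges]
        R = _correlation_matrix(analyte_ids, pairs)
        chol[t] = np.linalg.cholesky(R) if pairs else None
    pairs_adj = [(e.pair[0], e.pair[1], e.rho_adjacent) for e in edges]
    chol["adjacent"] = np.linalg.cholesky(_correlation_matrix(analyte_ids, pairs_adj))
    chol["IV"] = None  # no planted structure beyond stage III

    # --- latent log values --------------------------------------------------
    mu = rng.uniform(math.log(1e4), math.log(1e6), size=m)
    effect_shift = np.array([effects.get(mid, 0.0) for mid in analyte_ids]) * math.log(2)

    tissue_ids = [s.sample_id for s in samples]
    latent = pd.DataFrame(0.0, index=tissue_ids, columns=analyte_ids)

    def draw(sample_ids: list[str], key: str, shift: np.ndarray | None) -> None:
        z = rng.standard_normal((len(sample_ids), m))
        L = chol.get(key)
        if L is not None:
            z = z @ L.T
        vals = mu + cfg.noise_sd * z
        if shift is not None:
            vals = vals + shift
        latent.loc[sample_ids] = vals

    for t in ("I", "II", "III", "IV"):
        sids = [s.sample_id for s in samples
                if s.tissue_type == "tumor" and s.tnm_stage == t]
        if sids:
            draw(sids, t, effect_shift)
    adj_ids = [s.sample_id for s in samples if s.tissue_type == "adjacent"]
    draw(adj_ids, "adjacent", None)

    # clinical shifts are not planted by default; tests shift post hoc

    # --- QC replicates -------------------------------------------------------
    n_qc = max(3, len(tissue_ids) // cfg.qc_every)
    pooled = latent.mean(axis=0).to_numpy()
    sigma_qc = math.sqrt(math.log(1.0 + (cfg.qc_target_rsd / 100.0) ** 2))
    qc_log = pooled + sigma_qc * rng.standard_normal((n_qc, m))
    qc_ids = [f"QC_{i + 1:02d}" for i in range(n_qc)]
    for qid in qc_ids:
        samples.append(SampleRecord(qid, "pool", "QC"))

    # --- assemble raw responses ---------------------------------------------
    all_ids = tissue_ids + qc_ids
    log_values = np.vstack([latent.to_numpy(), qc_log])
    linear = np.exp(log_values)

    is_nominal = {IS_POS: 5e4, IS_NEG: 5e4}
    is_resp = pd.DataFrame(index=all_ids, columns=is_ids, dtype=float)
    for isd in is_ids:
        factors = np.exp(cfg.is_nuisance_sd * rng.standard_normal(len(all_ids)))
        is_resp[isd] = is_nominal.get(isd, 5e4) * factors

    weight = np.ones(len(all_ids))
    by_id = {s.sample_id: s for s in samples}
    for i, sid in enumerate(all_ids):
        rec = by_id[sid]
        if not rec.is_qc:
            weight[i] = rec.tissue_weight

    is_of = {mt.metabolite_id: mt.internal_standard_id for mt in mets}
    raw = np.empty_like(linear)
    for j, mid in enumerate(analyte_ids):
        raw[:, j] = linear[:, j] * is_resp[is_of[mid]].to_numpy() * weight
    table = pd.DataFrame(raw, index=all_ids, columns=analyte_ids)
    for isd in is_ids:
        table[isd] = is_resp[isd]

    monotone = [e.pair for e in edges if e.monotone]
    hub_counts: dict[str, int] = {}
    for e in edges:
        for mid in e.pair:
            hub_counts[mid] = hub_counts.get(mid, 0) + 1
    planted_hub = None
    if hub_counts:
        top = max(hub_counts.values())
        if top >= 3:
            planted_hub = sorted(h for h, c in hub_counts.items() if c == top)[0]

    truth = GroundTruth(
        differential=effects,
        planted_edges=list(edges),
        monotone_edges=monotone,
        planted_hub=planted_hub,
        latent_log=latent,
    )
    return PeakTable(table), samples, mets, truth
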