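"""Synthetic inputs for every pipeline stage.

The generators emulate the statistical structure of the study data —
two-class microarray expression with planted up/down-regulated genes,
binary functional attributes with a controlled association to a cancer-gene
label, interaction evidence with tunable support, and survival times with
group-dependent hazards — so the whole pipeline is testable end to end
without any external download. Fixed seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import NORMAL, TUMOR, ExpressionMatrix
from .interactome import InteractionEvidence
from .weights import ATTRIBUTES

#: Class-conditional attribute prevalences (p_cancer, p_noncancer).
#: Chosen to emulate the weak marginal associations seen in curated
#: cancer-gene annotation (hub status by far the strongest signal).
DEFAULT_PREVALENCE: dict[str, tuple[float, float]] = {
    "Meth": (0.14, 0.10),
    "SP": (0.20, 0.15),
    "PK": (0.12, 0.08),
    "TS": (0.25, 0.19),
    "PTM": (0.48, 0.40),
    "TF": (0.14, 0.09),
    "Hub": (0.40, 0.25),
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults give a desk-scale cohort: 1000 genes, 10 tumor vs 10 normal
    samples, 5% planted up- and 5% down-regulated genes shifted by 2 log2
    units against unit-SD Gaussian noise, and 100 known cancer genes.
    """

    n_genes: int = 1000
    n_tumor: int = 10
    n_normal: int = 10
    frac_up: float = 0.05
    frac_down: float = 0.05
    effect_size: float = 2.0  # mean log2 shift of planted genes
    noise_sd: float = 1.0  # per-gene SD on the log2 scale
    baseline_mean: float = 8.0  # mean log2 expression level
    baseline_sd: float = 2.0  # spread of per-gene baselines
    attribute_prevalence: dict = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    n_cancer_genes: int | None = None  # default: 10% of n_genes
    hazard_ratio: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_tumor < 2 or self.n_normal < 2:
            raise ValueError("need at least 2 samples per class")
        for name in ("frac_up", "frac_down"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        if self.frac_up + self.frac_down > 1:
            raise ValueError("frac_up + frac_down must be <= 1")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        for attr, (p1, p0) in self.attribute_prevalence.items():
            if not (0 <= p1 <= 1 and 0 <= p0 <= 1):
                raise ValueError(f"prevalence for {attr} outside [0,1]")
        if self.n_cancer_genes is None:
            self.n_cancer_genes = max(1, self.n_genes // 10)
        if not 0 <= self.n_cancer_genes <= self.n_genes:
            raise ValueError("n_cancer_genes must be in [0, n_genes]")


def gen_expression(
    cfg: SyntheticConfig,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Two-class expression matrix with planted differential genes.

    The first ``round(frac_up * n_genes)`` genes carry a +effect_size mean
    log2 shift in tumor samples, the next ``round(frac_down * n_genes)`` a
    -effect_size shift; the rest are null. Values are simulated on the
    log2 scale and exported on the *linear* scale (``is_log2=False``) so
    downstream code exercises the log2 preprocessing path.

    Returns the matrix and a gene -> {"up","down","none"} truth Series.
    """
    rng = np.random.default_rng(cfg.seed)
    n_up = int(round(cfg.frac_up * cfg.n_genes))
    n_down = int(round(cfg.frac_down * cfg.n_genes))
    genes = pd.Index(range(1, cfg.n_genes + 1), name="gene")
    truth = pd.Series("none", index=genes, dtype=object)
    truth.iloc[:n_up] = "up"
    truth.iloc[n_up : n_up + n_down] = "down"

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    n_samples = cfg.n_tumor + cfg.n_normal
    log2 = baseline[:, None] + rng.normal(
        0.0, cfg.noise_sd, size=(cfg.n_genes, n_samples)
    )
    shift = np.zeros(cfg.n_genes)
    shift[:n_up] = cfg.effect_size
    shift[n_up : n_up + n_down] = -cfg.effect_size
    log2[:, : cfg.n_tumor] += shift[:, None]

    samples = [f"T{i+1}" for i in range(cfg.n_tumor)] + [
        f"N{i+1}" for i in range(cfg.n_normal)
    ]
    classes = pd.Series(
        [TUMOR] * cfg.n_tumor + [NORMAL] * cfg.n_normal, index=samples
    )
    values = pd.DataFrame(2.0**log2, index=genes, columns=samples)
    return ExpressionMatrix(values, classes, is_log2=False), truth


def gen_attributes(cfg: SyntheticConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Binary gene x attribute table plus cancer-gene labels.

    The first ``n_cancer_genes`` genes are labelled cancer genes; each of
    the seven attributes is an independent Bernoulli draw at its
    class-conditional prevalence, so the expected phi of each attribute is
    given analytically by :func:`analytic_phi`.
    """
    missing = [a for a in ATTRIBUTES if a not in cfg.attribute_prevalence]
    if missing:
        raise ValueError(f"prevalence missing for attributes: {missing}")
    rng = np.random.default_rng(cfg.seed + 1)
    genes = pd.Index(range(1, cfg.n_genes + 1), name="gene")
    cancer = pd.Series(0, index=genes, dtype=int)
    cancer.iloc[: cfg.n_cancer_genes] = 1
    cols = {}
    for attr in ATTRIBUTES:
        p1, p0 = cfg.attribute_prevalence[attr]
        p = np.where(cancer.to_numpy() == 1, p1, p0)
        cols[attr] = (rng.random(cfg.n_genes) < p).astype(int)
    return pd.DataFrame(cols, index=genes), cancer


def analytic_phi(p_cancer: float, p_noncancer: float, frac_cancer: float) -> float:
    """Population phi of a binary attribute given its class-conditional
    prevalences and the cancer-gene fraction of the genome.

    Derived from the expected 2x2 table in proportions: with pi the cancer
    fraction and pbar the marginal prevalence,
    phi = (p1 - p0) * sqrt(pi (1-pi)) / sqrt(pbar (1-pbar)).
    """
    pi = frac_cancer
    pbar = pi * p_cancer + (1 - pi) * p_noncancer
    if pbar in (0.0, 1.0) or pi in (0.0, 1.0):
        raise ValueError("degenerate margins: phi undefined")
    return abs(p_cancer - p_noncancer) * np.sqrt(pi * (1 - pi)) / np.sqrt(
        pbar * (1 - pbar)
    )


@dataclass
class EvidenceProfile:
    """Per-edge probabilities of each kind of high-confidence support."""

    p_multi_db: float = 0.4  # second source database
    p_multi_method: float = 0.3  # second detection-method class
    p_domain: float = 0.2  # known domain-domain interaction
    p_multi_pmid: float = 0.3  # second independent publication

    DATABASES = ("dbA", "dbB", "dbC", "dbD", "dbE", "dbF")
    METHODS = ("biochemical", "biophysical", "imaging", "pca")

    def __post_init__(self) -> None:
        for name in ("p_multi_db", "p_multi_method", "p_domain", "p_multi_pmid"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} outside [0,1]")


def gen_interactions(
    n_proteins: int,
    n_edges: int,
    profile: EvidenceProfile | None = None,
    seed: int | None = None,
) -> list[InteractionEvidence]:
    """Random simple graph with per-edge evidence annotations.

    Edges are distinct unordered pairs (no self-loops). Each edge gets one
    or two source databases / detection methods / PMIDs and a domain flag,
    drawn independently per the profile, so the expected pass rate of each
    high-confidence rule equals the corresponding profile probability.
    """
    if profile is None:
        profile = EvidenceProfile()
    max_edges = n_proteins * (n_proteins - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"n_edges={n_edges} exceeds max {max_edges}")
    rng = np.random.default_rng(seed)
    ii, jj = np.triu_indices(n_proteins, k=1)
    chosen = np.sort(rng.choice(max_edges, size=n_edges, replace=False))
    pairs = [(f"P{ii[idx]+1}", f"P{jj[idx]+1}") for idx in chosen]
    records = []
    pmid_counter = 10000
    for a, b in pairs:
        n_db = 2 if rng.random() < profile.p_multi_db else 1
        dbs = set(rng.choice(profile.DATABASES, size=n_db, replace=False))
        n_m = 2 if rng.random() < profile.p_multi_method else 1
        methods = set(rng.choice(profile.METHODS, size=n_m, replace=False))
        n_p = 2 if rng.random() < profile.p_multi_pmid else 1
        pmids = {str(pmid_counter + k) for k in range(n_p)}
        pmid_counter += n_p
        domain = bool(rng.random() < profile.p_domain)
        records.append(
            InteractionEvidence(
                pair=frozenset((a, b)),
                databases=dbs,
                methods=methods,
                pmids=pmids,
                domain_support=domain,
            )
        )
    return records


def gen_clinical(
    n_samples: int,
    hazard_ratio: float,
    censor_rate: float = 0.2,
    seed: int | None = None,
    baseline_hazard: float = 1.0 / 365.0,
) -> pd.DataFrame:
    """Two-group survival cohort with exponential event times.

    The first half of the samples form the "good" (baseline-hazard) group,
    the second half the "poor" group with hazard ``hazard_ratio *
    baseline``. Censoring is an independent exponential clock with rate
    ``baseline * censor_rate / (1 - censor_rate)``, which censors roughly a
    ``censor_rate`` fraction of the baseline group; ``censor_rate=0``
    disables it. Times are in days.

    Returns a DataFrame with columns sample, time, event, group.
    """
    if n_samples < 4:
        raise ValueError("need at least 4 samples")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0,1)")
    rng = np.random.default_rng(seed)
    n_good = n_samples // 2
    groups = np.array(["good"] * n_good + ["poor"] * (n_samples - n_good))
    hazards = np.where(groups == "poor", hazard_ratio * baseline_hazard, baseline_hazard)
    event_times = rng.exponential(1.0 / hazards)
    if censor_rate > 0:
        c_rate = baseline_hazard * censor_rate / (1 - censor_rate)
        censor_times = rng.exponential(1.0 / c_rate, size=n_samples)
    else:
        censor_times = np.full(n_samples, np.inf)
    observed = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)
    return pd.DataFrame(
        {
            "sample": [f"S{i+1}" for i in range(n_samples)],
            "time": observed,
            "event": event,
            "group": groups,
        }
    )


# -- TSV export ------------------------------------------------------------


def write_attribute_tsv(path, attributes: pd.DataFrame, cancer: pd.Series) -> None:
    out = attributes.copy()
    out["cancer"] = cancer
    out.to_csv(path, sep="\t")


def read_attribute_tsv(path) -> tuple[pd.DataFrame, pd.Series]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df[list(ATTRIBUTES)], df["cancer"]


def write_interaction_tsv(path, records: list[InteractionEvidence]) -> None:
    rows = []
    for r in records:
        a, b = sorted(r.pair)
        rows.append(
            {
                "protein_a": a,
                "protein_b": b,
                "databases": ";".join(sorted(r.databases)),
                "methods": ";".join(sorted(r.methods)),
                "pmids": ";".join(sorted(r.pmids)),
                "domain_support": int(r.domain_support),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_interaction_tsv(path) -> list[InteractionEvidence]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records = []
    for _, row in df.iterrows():
        records.append(
            InteractionEvidence(
                pair=frozenset((row["protein_a"], row["protein_b"])),
                databases=set(filter(None, row["databases"].split(";"))),
                methods=set(filter(None, row["methods"].split(";"))),
                pmids=set(filter(None, row["pmids"].split(";"))),
                domain_support=bool(int(row["domain_support"] or 0)),
            )
        )
    return records
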