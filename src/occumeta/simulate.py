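"""Synthetic detection histories, metadata, and curation fixtures.

Everything here is generated with known truth so the whole pipeline is
testable without any external data: occupancy simulators drawing latent
states and detections through the same link functions the models fit, a
curation fixture with a hand-constructed disposition ledger, and a
parameter-recovery driver reporting bias, RMSE and interval coverage.

The covariate generators mirror the composition of the global metagenome
survey the models were designed around: ecosystem categories drawn with
probabilities 0.806 / 0.133 / 0.062 for environmental, host-associated and
engineered samples, latitudes uniform over the well-sampled band
[-60, 75] degrees, and database add dates uniform over roughly the first
5,000 days after 2006-01-01.  They emulate the marginal composition of
such a survey only — not its spatial clustering, sampling bias toward
North America and Europe, or any real sequence evolution.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import single as _single
from .history import DetectionHistory, design_matrix
from .multi import _log_state_probs
from .panels import MarkerPanel

ECOSYSTEM_PROBS = {"environmental": 0.806, "host-associated": 0.133, "engineered": 0.062}
LATITUDE_RANGE = (-60.0, 75.0)
ADD_DATE_RANGE = (0, 5000)  # days since the 2006-01-01 epoch


@dataclass
class SimulationConfig:
    """Truth and covariate-generator settings for one simulation.

    Coefficients are on the logit (single-species) or natural-parameter
    (two-species) scale, aligned with the design columns produced by the
    given term strings.  The convenience constructors cover the common
    constant-probability case.
    """

    n_sites: int
    n_surveys: int = 3
    seed: int = 0
    # single-species truth
    psi_terms: str = "1"
    psi_coefs: tuple[float, ...] = (0.0,)
    p_terms: str = "1"
    p_coefs: tuple[float, ...] = (0.0,)
    # two-species truth (natural parameters + detection intercepts)
    f1_terms: str = "1"
    f1_coefs: tuple[float, ...] = (0.0,)
    f2_terms: str = "1"
    f2_coefs: tuple[float, ...] = (0.0,)
    f12_terms: str = "1"
    f12_coefs: tuple[float, ...] = (0.0,)
    p1: float = 0.5
    p2: float = 0.5
    # covariate generators
    ecosystem_probs: dict = field(default_factory=lambda: dict(ECOSYSTEM_PROBS))
    latitude_range: tuple[float, float] = LATITUDE_RANGE
    add_date_range: tuple[int, int] = ADD_DATE_RANGE

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_surveys < 1:
            raise ValueError("n_sites and n_surveys must be positive")
        total = sum(self.ecosystem_probs.values())
        if abs(total - 1.0) > 0.01:
            raise ValueError("ecosystem probabilities must sum to 1")
        # tolerate rounded percentages (e.g. 80.6/13.3/6.2 sums to 100.1)
        if abs(total - 1.0) > 1e-9:
            self.ecosystem_probs = {k: v / total for k, v in self.ecosystem_probs.items()}
        for p in (self.p1, self.p2):
            if not 0.0 <= p <= 1.0:
                raise ValueError("detection probabilities must lie in [0, 1]")

    @classmethod
    def constant_single(cls, n_sites: int, psi: float, p: float, n_surveys: int = 3, seed: int = 0, **kw):
        return cls(
            n_sites=n_sites,
            n_surveys=n_surveys,
            seed=seed,
            psi_coefs=(float(_safe_logit(psi)),),
            p_coefs=(float(_safe_logit(p)),),
            **kw,
        )

    @classmethod
    def constant_multi(
        cls, n_sites: int, f1: float, f2: float, f12: float, p1: float, p2: float,
        n_surveys: int = 3, seed: int = 0, **kw,
    ):
        return cls(
            n_sites=n_sites,
            n_surveys=n_surveys,
            seed=seed,
            f1_coefs=(float(f1),),
            f2_coefs=(float(f2),),
            f12_coefs=(float(f12),),
            p1=p1,
            p2=p2,
            **kw,
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        raw = json.loads(text)
        for key in ("psi_coefs", "p_coefs", "f1_coefs", "f2_coefs", "f12_coefs",
                    "latitude_range", "add_date_range"):
            raw[key] = tuple(raw[key])
        return cls(**raw)


def _safe_logit(p: float) -> float:
    if p <= 0.0:
        return -745.0  # exp underflows to exactly 0
    if p >= 1.0:
        return 745.0
    return float(logit(p))


def _draw_covariates(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_sites
    cats = list(config.ecosystem_probs)
    probs = np.array([config.ecosystem_probs[c] for c in cats])
    eco = rng.choice(cats, size=n, p=probs)
    lat = rng.uniform(*config.latitude_range, size=n)
    lon = rng.uniform(-180.0, 180.0, size=n)
    nad = rng.integers(config.add_date_range[0], config.add_date_range[1] + 1, size=n)
    return pd.DataFrame(
        {
            "ecosystem": eco,
            "latitude": lat,
            "longitude": lon,
            "numeric_add_date": nad,
            "sqrt_numeric_add_date": np.sqrt(nad),
        },
        index=pd.Index([f"sim{i:06d}" for i in range(n)], name="site_id"),
    )


def _linear(site_table: pd.DataFrame, terms: str, coefs) -> np.ndarray:
    x, names, _ = design_matrix(site_table, terms)
    coefs = np.asarray(coefs, dtype=float)
    if coefs.size != x.shape[1]:
        raise ValueError(f"{coefs.size} coefficients for {x.shape[1]} design columns {names}")
    return x @ coefs


@dataclass
class SingleSimResult:
    history: DetectionHistory
    site_table: pd.DataFrame
    truth: dict


def simulate_single(config: SimulationConfig) -> SingleSimResult:
    """Covariates -> psi_i, p_i -> latent z_i -> detections y_ik.

    One seeded generator drives covariates, latent states, and detections
    in a fixed order, so the seed pins the entire draw.
    """
    rng = np.random.default_rng(config.seed)
    site_table = _draw_covariates(config, rng)
    psi = expit(_linear(site_table, config.psi_terms, config.psi_coefs))
    p = expit(_linear(site_table, config.p_terms, config.p_coefs))
    z = rng.random(config.n_sites) < psi
    y = (rng.random((config.n_sites, config.n_surveys)) < p[:, None]) & z[:, None]
    markers = tuple(f"survey{k+1}" for k in range(config.n_surveys))
    hist = DetectionHistory(list(site_table.index), y.astype(np.int8), markers)
    truth = {"z": z.astype(int), "psi": psi, "p": p, "config": config}
    return SingleSimResult(hist, site_table, truth)


@dataclass
class MultiSimResult:
    history1: DetectionHistory
    history2: DetectionHistory
    site_table: pd.DataFrame
    truth: dict


def simulate_multi(config: SimulationConfig) -> MultiSimResult:
    """Joint latent state per site from the log-linear model, then
    per-species detections with intercept-only probabilities."""
    rng = np.random.default_rng(config.seed)
    site_table = _draw_covariates(config, rng)
    f = np.column_stack(
        [
            _linear(site_table, config.f1_terms, config.f1_coefs),
            _linear(site_table, config.f2_terms, config.f2_coefs),
            _linear(site_table, config.f12_terms, config.f12_coefs),
        ]
    )
    psis = np.exp(_log_state_probs(f))  # columns: 00, 10, 01, 11
    u = rng.random(config.n_sites)
    cum = np.cumsum(psis, axis=1)
    state = (u[:, None] >= cum).sum(axis=1)  # index into (00, 10, 01, 11)
    z1 = np.isin(state, (1, 3))
    z2 = np.isin(state, (2, 3))
    y1 = (rng.random((config.n_sites, config.n_surveys)) < config.p1) & z1[:, None]
    y2 = (rng.random((config.n_sites, config.n_surveys)) < config.p2) & z2[:, None]
    m1 = tuple(f"s1_survey{k+1}" for k in range(config.n_surveys))
    m2 = tuple(f"s2_survey{k+1}" for k in range(config.n_surveys))
    sites = list(site_table.index)
    truth = {"z1": z1.astype(int), "z2": z2.astype(int), "state_probs": psis, "config": config}
    return MultiSimResult(
        DetectionHistory(sites, y1.astype(np.int8), m1),
        DetectionHistory(sites, y2.astype(np.int8), m2),
        site_table,
        truth,
    )


def to_occupancy_table(result: MultiSimResult, panel1: MarkerPanel, panel2: MarkerPanel) -> pd.DataFrame:
    """Flatten a two-panel simulation to the occupancy-table dialect."""
    from .history import DATE_EPOCH
    import datetime as dt

    st = result.site_table
    df = pd.DataFrame({"metagenome_id": list(st.index)})
    for j, m in enumerate(panel1.markers):
        df[m] = result.history1.y[:, j]
    for j, m in enumerate(panel2.markers):
        df[m] = result.history2.y[:, j]
    df["ecosystem"] = st["ecosystem"].to_numpy()
    df["longitude"] = st["longitude"].to_numpy()
    df["latitude"] = st["latitude"].to_numpy()
    df["add_date"] = [
        (DATE_EPOCH + dt.timedelta(days=int(d))).isoformat() for d in st["numeric_add_date"]
    ]
    df["sample_date"] = df["add_date"]
    return df


# ---------------------------------------------------------------------------
# Curation fixture
# ---------------------------------------------------------------------------

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))


@dataclass
class CurationFixture:
    """In-memory curation inputs with a known disposition ledger."""

    panel: MarkerPanel
    ref_fasta: str
    label_table: pd.DataFrame  # subject_id, label, marker
    cand_fasta: str
    hits_text: str  # outfmt-6 TSV
    newick: str
    expected: pd.DataFrame  # seq_id, reason

    def write(self, outdir) -> dict:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "references": outdir / "references.faa",
            "labels": outdir / "labels.tsv",
            "candidates": outdir / "candidates.faa",
            "hits": outdir / "hits.tsv",
            "tree": outdir / "tree.nwk",
            "expected": outdir / "expected_dispositions.tsv",
        }
        paths["references"].write_text(self.ref_fasta)
        self.label_table.to_csv(paths["labels"], sep="\t", index=False)
        paths["candidates"].write_text(self.cand_fasta)
        paths["hits"].write_text(self.hits_text)
        paths["tree"].write_text(self.newick)
        self.expected.to_csv(paths["expected"], sep="\t", index=False)
        return {k: str(v) for k, v in paths.items()}


def make_curation_fixtures(seed: int = 0) -> CurationFixture:
    """A single-marker fixture covering every disposition reason.

    True-positive references have lengths 550/560/580, so the length
    window is [500, 630].  Candidates are laid out so that running
    ``curate`` reproduces the expected ledger exactly: clean keeps, a
    too-short and a too-long sequence, a false-positive top hit, a
    candidate with no hit at all, one whose nearest labeled tree leaf is a
    false positive, and one on an extremely long branch.
    """
    rng = np.random.default_rng(seed)
    panel = MarkerPanel("MCR", ("McrA",), ("K00399",))

    refs = {
        "refTP1": (550, "true_positive"),
        "refTP2": (560, "true_positive"),
        "refTP3": (580, "true_positive"),
        "refFP_anme": (555, "false_positive"),  # ANME-type MCR homolog
        "refFP_amo": (540, "false_positive"),  # off-target homolog
    }
    ref_fasta = "".join(
        f">{rid} synthetic reference\n{_random_protein(rng, ln)}\n" for rid, (ln, _) in refs.items()
    )
    label_table = pd.DataFrame(
        {
            "subject_id": list(refs),
            "label": [lab for _, lab in refs.values()],
            "marker": ["McrA"] * len(refs),
        }
    )

    # (local name, metagenome, length, expected reason)
    layout = [
        ("clean1", "mgA", 550, "kept"),
        ("clean2", "mgA", 560, "kept"),
        ("clean3", "mgB", 575, "kept"),
        ("clean4", "mgC", 505, "kept"),
        ("clean5", "mgD", 620, "kept"),
        ("clean6", "mgE", 555, "kept"),
        ("clean7", "mgF", 565, "kept"),
        ("clean8", "mgG", 585, "kept"),
        ("clean9", "mgH", 545, "kept"),
        ("clean10", "mgB", 552, "kept"),
        ("clean11", "mgC", 558, "kept"),
        ("clean12", "mgD", 572, "kept"),
        ("short1", "mgA", 499, "too_short"),
        ("short2", "mgE", 300, "too_short"),
        ("long1", "mgB", 631, "too_long"),
        ("long2", "mgF", 900, "too_long"),
        ("fptop1", "mgC", 550, "fp_top_hit"),
        ("fptop2", "mgG", 560, "fp_top_hit"),
        ("nohit1", "mgD", 555, "no_hit"),
        ("treefp1", "mgH", 556, "nearest_fp"),
        ("treelong1", "mgA", 557, "long_branch"),
    ]
    cand_rows = []
    for local, mg, ln, reason in layout:
        seq_id = f"{mg}|McrA|{local}"
        cand_rows.append((seq_id, mg, ln, reason))
    cand_fasta = "".join(
        f">{sid}\n{_random_protein(rng, ln)}\n" for sid, _, ln, _ in cand_rows
    )

    # Hit table: every non-length-removed candidate except nohit1 gets hits.
    hit_lines = []

    def hit(q, s, score):
        hit_lines.append(
            f"{q}\t{s}\t95.0\t500\t10\t1\t1\t500\t1\t500\t1e-100\t{score:.1f}"
        )

    for sid, _, _, reason in cand_rows:
        if reason in ("too_short", "too_long", "no_hit"):
            continue  # length-removed never reach the search; nohit1 is absent
        if reason == "fp_top_hit":
            hit(sid, "refFP_amo", 400.0)
            hit(sid, "refTP1", 350.0)
        else:
            hit(sid, "refTP1", 420.0)
            hit(sid, "uniref_background", 300.0)
    hits_text = "\n".join(hit_lines) + "\n"

    # Tree over the post-top-hit survivors plus references.  treefp1 sits
    # next to the ANME false positive; treelong1 has a terminal branch two
    # orders of magnitude above the rest.
    clean_ids = [sid for sid, _, _, r in cand_rows if r == "kept"]
    tp_clade = ",".join(
        f"{sid}:0.02" for sid in clean_ids
    )
    newick = (
        "(("
        + tp_clade
        + ",refTP1:0.01,refTP2:0.01,refTP3:0.015):0.05,"
        + "(refFP_anme:0.02,mgH|McrA|treefp1:0.02):0.30,"
        + "refFP_amo:0.40,"
        + "mgA|McrA|treelong1:5.0);"
    )

    expected = pd.DataFrame(
        {"seq_id": [sid for sid, _, _, _ in cand_rows], "reason": [r for _, _, _, r in cand_rows]}
    )
    return CurationFixture(
        panel=panel,
        ref_fasta=ref_fasta,
        label_table=label_table,
        cand_fasta=cand_fasta,
        hits_text=hits_text,
        newick=newick,
        expected=expected,
    )


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

def recovery_experiment(
    config: SimulationConfig,
    n_replicates: int,
    n_starts: int = 2,
) -> pd.DataFrame:
    """Repeat simulate -> fit and summarize estimator behavior.

    Returns one row per parameter with truth, mean estimate, bias, RMSE and
    95% Wald-interval coverage.  When both designs are intercept-only, rows
    for psi and p on the probability scale are included (intervals mapped
    through the inverse logit, matching ``predict_occupancy``).  Replicates
    that fail to converge are counted and excluded, never fatal.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    truth_beta = np.concatenate([config.psi_coefs, config.p_coefs])
    est = []
    ses = []
    n_fail = 0
    spec = _single.OccuModelSpec(psi_terms=config.psi_terms, p_terms=config.p_terms)
    for r in range(n_replicates):
        cfg = dataclasses.replace(config, seed=config.seed + r)
        sim = simulate_single(cfg)
        try:
            f = _single.fit(sim.history, sim.site_table, spec, n_starts=n_starts, seed=cfg.seed)
        except (RuntimeError, ValueError):
            n_fail += 1
            continue
        if not f.converged:
            n_fail += 1
            continue
        est.append(f.coefs)
        ses.append(f.se())
    if not est:
        raise RuntimeError("no replicate converged")
    est_arr = np.array(est)
    se_arr = np.array(ses)

    rows = []
    names = [f"psi:{t}" for t in _coef_names(config.psi_terms, len(config.psi_coefs))]
    names += [f"p:{t}" for t in _coef_names(config.p_terms, len(config.p_coefs))]
    for j, name in enumerate(names):
        lo = est_arr[:, j] - _single.Z95 * se_arr[:, j]
        hi = est_arr[:, j] + _single.Z95 * se_arr[:, j]
        rows.append(
            {
                "parameter": name,
                "scale": "logit",
                "truth": truth_beta[j],
                "mean_estimate": est_arr[:, j].mean(),
                "bias": est_arr[:, j].mean() - truth_beta[j],
                "rmse": float(np.sqrt(((est_arr[:, j] - truth_beta[j]) ** 2).mean())),
                "coverage": float(((lo <= truth_beta[j]) & (truth_beta[j] <= hi)).mean()),
            }
        )
    if config.psi_terms.strip() == "1" and config.p_terms.strip() == "1":
        for j, (name, truth) in enumerate(
            [("psi", expit(config.psi_coefs[0])), ("p", expit(config.p_coefs[0]))]
        ):
            prob = expit(est_arr[:, j])
            lo = expit(est_arr[:, j] - _single.Z95 * se_arr[:, j])
            hi = expit(est_arr[:, j] + _single.Z95 * se_arr[:, j])
            rows.append(
                {
                    "parameter": name,
                    "scale": "probability",
                    "truth": truth,
                    "mean_estimate": prob.mean(),
                    "bias": prob.mean() - truth,
                    "rmse": float(np.sqrt(((prob - truth) ** 2).mean())),
                    "coverage": float(((lo <= truth) & (truth <= hi)).mean()),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["n_replicates"] = n_replicates
    out.attrs["n_failed"] = n_fail
    return out


def _coef_names(terms: str, width: int) -> list[str]:
    if terms.strip() == "1":
        return ["(Intercept)"]
    return [f"b{j}" for j in range(width)]
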