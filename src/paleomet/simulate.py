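"""Synthetic trees and co-evolving traits for end-to-end testing.

The generator emulates the structure of the reference analysis: a
time-calibrated amniote phylogeny (pure-birth, ultrametric) on which
log10 mass-independent MMR and log10 nutrient-artery blood flow co-evolve
by correlated bivariate Brownian motion, with independent Gaussian
measurement noise at the tips.  A subset of tips is masked as "fossils":
their response is deleted, their blood flow is kept (optionally re-encoded
as a foramen aperture area so the full area -> flow chain is exercised),
and the deleted values are retained in a truth table for scoring.

Defaults mirror the reference dataset: 43 tips in three clades (15
synapsids, 14 non-avian sauropsids, 14 avians), a birth rate giving an
amniote-like root age of roughly 300 Myr, Brownian rates of 0.001 per Myr
per trait with cross-correlation 0.8, residual noise of 0.1 log10 units,
and 2 fossil tips.
"""
from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .allometry import DEFAULT_CLADE_EXPONENTS
from .hemodynamics import radius_from_flow
from .inference import forward_select, loocv, retrodict
from .pem import build_pem, location_scores, unrepresented_length
from .phylo import GraftSpec, PhyloTree, brownian_rate, graft_fossil, prune_tip, prune_tips

__all__ = [
    "SimulationConfig",
    "SimBundle",
    "simulate_tree",
    "simulate_traits",
    "make_fossil_cases",
    "make_bundle",
    "write_bundle",
    "calibration_experiment",
]



@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset."""

    n_tips: int = 43
    birth_rate: float = 0.0125            # Myr^-1
    root_log_mmr_mi: float = 1.0          # log10 mLO2 h^-1 g^-b
    root_log_q: float = -2.0              # log10 mL s^-1
    rate_mmr: float = 0.001               # Brownian rate, per Myr
    rate_q: float = 0.001
    correlation: float = 0.8              # Brownian cross-correlation
    noise_sd: float = 0.1                 # tip noise, log10 units
    n_fossils: int = 2
    fossil_mode: str = "contemporaneous"  # or "grafted" (older tips)
    allometric_exponent: float = 0.87     # b used to dress MMR with mass
    log_mass_mean: float = 3.0            # log10 g
    log_mass_sd: float = 1.0
    lumen_fraction: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 6:
            raise ValueError("need at least 6 tips")
        if not self.n_fossils < self.n_tips / 2:
            raise ValueError("fossil count must be < half the tip count")
        if self.birth_rate <= 0:
            raise ValueError("birth rate must be > 0")
        if self.fossil_mode not in ("contemporaneous", "grafted"):
            raise ValueError("fossil_mode must be 'contemporaneous' or 'grafted'")
        s = self.sigma
        if np.any(np.linalg.eigvalsh(s) < -1e-12):
            raise ValueError("Brownian rate matrix must be positive semi-definite")

    @property
    def sigma(self) -> np.ndarray:
        """2x2 Brownian rate matrix for (log MMR_mi, log Q)."""
        cov = self.correlation * math.sqrt(self.rate_mmr * self.rate_q)
        return np.array([[self.rate_mmr, cov], [cov, self.rate_q]])


def simulate_tree(config: SimulationConfig, rng: np.random.Generator | None = None) -> PhyloTree:
    """Pure-birth (Yule) tree with ``n_tips`` contemporaneous tips.

    Lineages split at rate ``birth_rate`` each; after the (n-1)-th split
    the tree is extended by one more exponential wait and cut, so all tips
    end at the same height (ultrametric).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, lam = config.n_tips, config.birth_rate
    parent: dict[int, int | None] = {0: None}
    children: dict[int, list[int]] = {0: [1, 2], 1: [], 2: []}
    blen: dict[int, float] = {}
    start = {1: 0.0, 2: 0.0}
    parent.update({1: 0, 2: 0})
    active = [1, 2]
    nxt = 3
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / (lam * len(active)))
        idx = int(rng.integers(len(active)))
        v = active[idx]
        blen[v] = t - start[v]
        c1, c2 = nxt, nxt + 1
        nxt += 2
        children[v] = [c1, c2]
        children[c1] = []
        children[c2] = []
        parent[c1] = v
        parent[c2] = v
        start[c1] = t
        start[c2] = t
        active[idx] = c1
        active.append(c2)
    t += rng.exponential(1.0 / (lam * n))
    label = {}
    width = len(str(n))
    order = sorted(active)
    for i, v in enumerate(order):
        blen[v] = t - start[v]
        label[v] = f"t{i + 1:0{width}d}"
    return PhyloTree(parent, children, blen, label, 0)


def simulate_traits(
    tree: PhyloTree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Bivariate Brownian traits at the tips, plus tip measurement noise.

    Returns a DataFrame indexed by taxon with columns ``log_mmr_mi`` and
    ``log_q``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    sigma = config.sigma
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(sigma)
        L = vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))
    state = {tree.root: np.array([config.root_log_mmr_mi, config.root_log_q])}
    for v in tree.preorder():
        if v == tree.root:
            continue
        inc = L @ rng.standard_normal(2) * math.sqrt(tree.blen[v])
        state[v] = state[tree.parent[v]] + inc
    tips = tree.tip_ids()
    vals = np.array([state[v] for v in tips])
    if config.noise_sd > 0:
        vals = vals + rng.normal(0.0, config.noise_sd, size=vals.shape)
    return pd.DataFrame(
        vals, columns=["log_mmr_mi", "log_q"],
        index=pd.Index([tree.label[v] for v in tips], name="taxon"),
    )


def _assign_clades(tree: PhyloTree) -> dict[str, str]:
    """Split the preorder tip sequence into three contiguous clade blocks
    sized like the reference dataset (15/14/14, scaled)."""
    labels = tree.tip_labels()
    n = len(labels)
    sizes = [round(n * f) for f in (15 / 43, 14 / 43)]
    sizes.append(n - sum(sizes))
    out: dict[str, str] = {}
    pos = 0
    for clade, s in zip(("synapsid", "non_avian_sauropsid", "avian"), sizes):
        for lab in labels[pos:pos + s]:
            out[lab] = clade
        pos += s
    return out


def make_fossil_cases(
    tree: PhyloTree,
    traits: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    fossil_labels: list[str] | None = None,
    encode_foramen: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mask tips as fossils; return (species dataset, truth table).

    The dataset carries the pipeline's CSV schema (taxon, clade, mass_g,
    mmr_mlo2_h, q_ml_s, foramen_area_mm2).  Fossils lose their response
    (and mass) but keep blood flow — by default re-encoded as a foramen
    aperture area by inverting the hemodynamic chain.  The truth table
    records the deleted response values.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    labels = tree.tip_labels()
    if fossil_labels is None:
        fossil_labels = [
            str(x) for x in rng.choice(labels, size=config.n_fossils, replace=False)
        ]
    clades = _assign_clades(tree)
    b = config.allometric_exponent
    log_mass = rng.normal(config.log_mass_mean, config.log_mass_sd, len(labels))
    rows = []
    for lab, lm in zip(labels, log_mass):
        mmr_mi = 10.0 ** traits.loc[lab, "log_mmr_mi"]
        q = 10.0 ** traits.loc[lab, "log_q"]
        mass = 10.0 ** lm
        is_fossil = lab in fossil_labels
        area = math.nan
        q_out = q
        if is_fossil and encode_foramen:
            r = radius_from_flow(q)
            area = math.pi * r * r / config.lumen_fraction
            q_out = math.nan
        rows.append(
            {
                "taxon": lab,
                "clade": clades[lab],
                "mass_g": math.nan if is_fossil else mass,
                "mmr_mlo2_h": math.nan if is_fossil else mmr_mi * mass**b,
                "q_ml_s": q_out,
                "foramen_area_mm2": area,
            }
        )
    dataset = pd.DataFrame(rows).set_index("taxon")
    truth = pd.DataFrame(
        {
            "taxon": fossil_labels,
            "log_mmr_mi": [traits.loc[f, "log_mmr_mi"] for f in fossil_labels],
            "mmr_mi": [10.0 ** traits.loc[f, "log_mmr_mi"] for f in fossil_labels],
        }
    ).set_index("taxon")
    return dataset, truth


@dataclasses.dataclass
class SimBundle:
    """A complete synthetic study: inputs for the pipeline plus the truth."""

    config: SimulationConfig
    full_tree: PhyloTree            # fossils still attached as tips
    extant_tree: PhyloTree          # fossils pruned
    fossil_specs: list[GraftSpec]   # re-graft positions for the fossils
    dataset: pd.DataFrame
    truth: pd.DataFrame


def make_bundle(config: SimulationConfig) -> SimBundle:
    """Simulate tree + traits, mask fossils, and pre-compute graft specs."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config, rng)
    labels = tree.tip_labels()
    fossil_labels = [str(x) for x in rng.choice(labels, size=config.n_fossils, replace=False)]
    if config.fossil_mode == "grafted":
        # age the fossil tips by truncating their terminal branches
        t = tree.copy()
        for lab in fossil_labels:
            v = t.find(lab)
            t.blen[v] *= float(rng.uniform(0.3, 0.8))
        tree = t
    traits = simulate_traits(tree, config, rng)
    dataset, truth = make_fossil_cases(
        tree, traits, config, rng, fossil_labels=fossil_labels
    )
    extant, spec_map = prune_tips(tree, fossil_labels)
    specs = [spec_map[lab] for lab in fossil_labels]
    # label unlabeled internal attachment nodes so specs survive Newick I/O
    extant = extant.copy()
    counter = 0
    resolved: list[GraftSpec] = []
    for spec in specs:
        node = extant.find(spec.attach)
        lab = extant.label.get(node)
        if not lab:
            counter += 1
            lab = f"anc_{counter}"
            extant.label[node] = lab
        resolved.append(dataclasses.replace(spec, attach=lab))
    return SimBundle(config, tree, extant, resolved, dataset, truth)


def write_bundle(config: SimulationConfig, outdir: str | Path) -> SimBundle:
    """Write a bundle as the CSV/Newick/YAML files the pipeline consumes."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = make_bundle(config)
    bundle.dataset.to_csv(out / "species.csv")
    (out / "tree.nwk").write_text(bundle.extant_tree.write_newick() + "\n")
    bundle.truth.to_csv(out / "truth.csv")
    fossils = []
    for spec in bundle.fossil_specs:
        area = bundle.dataset.loc[spec.label, "foramen_area_mm2"]
        q = bundle.dataset.loc[spec.label, "q_ml_s"]
        entry: dict = {
            "label": spec.label,
            "attach": spec.attach,
            "stem_length": float(spec.stem_length),
        }
        if spec.attach_time is not None:
            entry["attach_time"] = float(spec.attach_time)
        if not math.isnan(area):
            entry["foramen_area_mm2"] = float(area)
        elif not math.isnan(q):
            entry["q_ml_s"] = float(q)
        fossils.append(entry)
    run_cfg = {
        "species_csv": "species.csv",
        "tree_newick": "tree.nwk",
        "fossils": fossils,
        "hemodynamics": {"lumen_fraction": config.lumen_fraction},
        "output_dir": "results",
        "seed": config.seed,
    }
    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(run_cfg, fh, sort_keys=False)
    return bundle


def calibration_experiment(
    n_reps: int = 200,
    seed: int = 0,
    config: SimulationConfig | None = None,
    interval: str = "prediction",
    level: float = 0.95,
    alpha: float = 0.05,
    run_loocv: bool = True,
) -> dict:
    """Interval-calibration and LOOCV-validity experiment on synthetic data.

    Each replicate simulates a tree and correlated traits, masks
    ``config.n_fossils`` tips, fits the forward-selected eigenvector model
    on the remaining tips, and scores (a) whether each masked tip's
    interval covers its realized value, and (b) the LOOCV differences and
    their paired-test p-value.  Returns coverage, overall LOOCV bias and
    the paired-test rejection rate at ``alpha``.
    """
    if config is None:
        config = SimulationConfig(n_tips=40, n_fossils=4)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_reps)
    covered = 0
    n_intervals = 0
    all_diffs: list[float] = []
    rejections = 0
    n_tests = 0
    for child in children:
        rng = np.random.default_rng(child)
        tree = simulate_tree(config, rng)
        traits = simulate_traits(tree, config, rng)
        labels = tree.tip_labels()
        fossils = [str(x) for x in rng.choice(labels, size=config.n_fossils, replace=False)]
        extant, spec_map = prune_tips(tree, fossils)
        specs = [spec_map[lab] for lab in fossils]
        basis = build_pem(extant)
        order = basis.tip_labels
        y = traits.loc[order, "log_mmr_mi"].to_numpy(float)
        z = traits.loc[order, "log_q"].to_numpy(float)
        fit = forward_select(y, basis, z)
        rate = brownian_rate(extant, dict(zip(order, y)))
        for lab, spec in zip(fossils, specs):
            grafted = graft_fossil(extant, spec)
            scores = location_scores(basis, grafted, lab)
            stem = unrepresented_length(grafted, lab)
            r = retrodict(
                fit, scores, z_fossil=float(traits.loc[lab, "log_q"]),
                level=level, kind=interval, label=lab,
                stem_variance=rate * basis.psi**2 * stem ** (1.0 - basis.a),
            )
            truth = float(traits.loc[lab, "log_mmr_mi"])
            covered += int(r.lower_log10 <= truth <= r.upper_log10)
            n_intervals += 1
        if run_loocv:
            df = traits.loc[order].copy()
            report = loocv(df, extant, full_fit=fit)
            all_diffs.extend(
                f.observed - f.predicted for f in report.folds if f.ok
            )
            n_tests += 1
            rejections += int(report.pvalue < alpha)
    out = {
        "n_reps": n_reps,
        "coverage": covered / n_intervals,
        "n_intervals": n_intervals,
    }
    if run_loocv:
        out["loocv_bias"] = float(np.mean(all_diffs))
        out["loocv_n_folds"] = len(all_diffs)
        out["type1_rate"] = rejections / n_tests
    return out
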