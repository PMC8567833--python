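"""End-to-end studies: connectomes vs. generative models, and group contrasts.

Two orchestrated analyses mirror the two halves of the framework:

* :func:`run_model_comparison` — binarize each subject's FA matrix, keep the
  largest component, compute its spectral-entropy curve under CRW and/or
  MERW, fit the four generative models per subject, sample ensembles, and
  compare pooled model entropy against the data (curves, entropic ratios and
  per-τ Welch/Holm/posterior tables).
* :func:`run_group_comparison` — per-group entropy curves, group-vs-reference
  entropic ratios and test tables, plus per-group steady-state node tables
  (the brain-map surrogate): each subject is binarized, stationary vectors
  are averaged across the group.

A master seed drives a seed-sequence tree (per subject, per model, per
stage), so any sub-computation can be reproduced in isolation.  Every output
CSV carries a hash of the configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import models as gm
from .cohort import CohortSpec, generate_cohort
from .entropy import EntropyCurve, entropic_ratio, entropy_curve
from .io import (
    BinaryGraph,
    WeightedConnectome,
    binarize_fa,
    largest_component,
    read_weighted_matrix,
)
from .stats import per_tau_tests
from .walks import WalkKind, walk_system

logger = logging.getLogger("connectropy")

__all__ = ["RunConfig", "run_model_comparison", "run_group_comparison"]


@dataclass
class RunConfig:
    """Configuration for an end-to-end run.

    Either ``cohort`` (synthetic) or ``manifest`` (a CSV with columns
    subject, group, file of dense FA matrices) must be provided.
    """

    cohort: CohortSpec | None = None
    manifest: str | None = None
    walks: tuple[str, ...] = ("crw", "merw")
    tau_min: float = 0.1
    tau_max: float = 1e3
    tau_points: int = 60
    realizations: int = 100
    binarization_draws: int = 1
    model_families: tuple[str, ...] = ("ERM", "CM", "DCSBM", "HM")
    holm_family_across_tau: bool = False
    outdir: str = "connectropy_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.realizations < 1 or self.binarization_draws < 1:
            raise ValueError("realizations and binarization draws must be >= 1")
        if self.tau_points < 2 or self.tau_min <= 0 or self.tau_max <= self.tau_min:
            raise ValueError("invalid tau grid")
        unknown = set(self.model_families) - set(gm.MODEL_FAMILIES)
        if unknown:
            raise ValueError(f"unknown model families: {sorted(unknown)}")

    @property
    def taus(self) -> np.ndarray:
        return np.geomspace(self.tau_min, self.tau_max, self.tau_points)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _load_subjects(cfg: RunConfig) -> list[tuple[str, WeightedConnectome]]:
    if cfg.cohort is not None:
        return generate_cohort(cfg.cohort)
    if cfg.manifest is None:
        raise ValueError("config needs either a cohort spec or a manifest")
    mpath = Path(cfg.manifest)
    table = pd.read_csv(mpath)
    out = []
    for _, row in table.iterrows():
        conn = read_weighted_matrix(mpath.parent / row["file"])
        out.append((str(row["group"]), conn))
    return out


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with path.open("w") as fh:
        fh.write(f"# config_hash: {cfg_hash}\n")
        df.to_csv(fh, index=False)


def _binarized_graphs(
    subjects: list[tuple[str, WeightedConnectome]],
    cfg: RunConfig,
    seeds: list[np.random.SeedSequence],
) -> list[tuple[str, list[BinaryGraph]]]:
    """One (or several) binarized largest-component graphs per subject."""
    out = []
    for (label, conn), sseed in zip(subjects, seeds):
        draws = []
        rng = np.random.default_rng(sseed)
        for _ in range(cfg.binarization_draws):
            g = binarize_fa(conn, rng)
            gc = largest_component(g)
            removed = g.n_nodes - gc.n_nodes
            if removed:
                logger.info(
                    "subject (%s): removed %d node(s) outside the largest "
                    "component", label, removed,
                )
            draws.append(gc)
        out.append((label, draws))
    return out


def _subject_curves(
    graphs: list[tuple[str, list[BinaryGraph]]],
    kind: WalkKind,
    taus: np.ndarray,
) -> tuple[list[str], list[EntropyCurve]]:
    labels, curves = [], []
    for label, draws in graphs:
        per_draw = np.vstack([entropy_curve(g, kind, taus).S for g in draws])
        mean_curve = EntropyCurve(
            taus, per_draw.mean(axis=0), draws[0].n_nodes, kind
        )
        labels.append(label)
        curves.append(mean_curve)
    return labels, curves


def run_model_comparison(cfg: RunConfig) -> dict:
    """Compare empirical (or synthetic-cohort) connectomes with the four
    generative-model ensembles; write curves, ratios and test tables."""
    t0 = time.time()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = cfg.config_hash()
    taus = cfg.taus
    subjects = _load_subjects(cfg)
    root = np.random.SeedSequence(cfg.seed)
    bin_seeds = root.spawn(len(subjects))
    graphs = _binarized_graphs(subjects, cfg, bin_seeds)
    n_nodes = int(np.median([d[0].n_nodes for _, d in graphs]))
    logger.info("model comparison: %d subjects, N ~ %d", len(graphs), n_nodes)

    results: dict = {"taus": taus, "config_hash": h}
    curve_rows = []
    test_frames = []
    for kname in cfg.walks:
        kind = WalkKind(kname)
        _, data_curves = _subject_curves(graphs, kind, taus)
        data_mat = np.vstack([c.S for c in data_curves])
        curve_rows.append(
            pd.DataFrame(
                {
                    "tau": taus,
                    "value": data_mat.mean(axis=0),
                    "sd": data_mat.std(axis=0, ddof=1)
                    if data_mat.shape[0] > 1
                    else 0.0,
                    "group": "data",
                    "walk_kind": kind.value,
                }
            )
        )
        model_samples: dict[str, np.ndarray] = {}
        for fam in cfg.model_families:
            fam_id = sorted(gm.MODEL_FAMILIES).index(fam)
            fam_seed_fit, fam_seed_sample = np.random.SeedSequence(
                (cfg.seed, fam_id, 1)
            ).spawn(2)
            fit_rngs = np.random.default_rng(fam_seed_fit)
            fitted = []
            for _, draws in graphs:
                g = draws[0]
                cls = gm.MODEL_FAMILIES[fam]
                kwargs = {}
                if fam in ("DCSBM", "HM"):
                    kwargs["random_state"] = int(
                        fit_rngs.integers(0, 2**31 - 1)
                    )
                fitted.append(cls(**kwargs).fit(g))
            ens = gm.ensemble_entropy(
                fitted,
                cfg.realizations,
                kind,
                taus,
                np.random.default_rng(fam_seed_sample),
            )
            model_samples[fam] = ens.samples
            curve_rows.append(
                pd.DataFrame(
                    {
                        "tau": taus,
                        "value": ens.mean,
                        "sd": ens.sd,
                        "group": fam,
                        "walk_kind": kind.value,
                    }
                )
            )
            ratio = entropic_ratio(ens.curves(), data_curves)
            ratio["model"] = fam
            ratio["walk_kind"] = kind.value
            results.setdefault("ratios", []).append(ratio)
        tests = per_tau_tests(
            model_samples,
            data_mat,
            taus,
            n_nodes,
            family_across_tau=cfg.holm_family_across_tau,
        )
        tests["walk_kind"] = kind.value
        test_frames.append(tests)
        results[f"data_curves_{kind.value}"] = data_mat
        results[f"model_samples_{kind.value}"] = model_samples

    curves_df = pd.concat(curve_rows, ignore_index=True)
    tests_df = pd.concat(test_frames, ignore_index=True)
    ratios_df = pd.concat(results.pop("ratios"), ignore_index=True)
    _write_csv(curves_df, outdir / "entropy_curves.csv", h)
    _write_csv(ratios_df, outdir / "entropic_ratios.csv", h)
    _write_csv(tests_df, outdir / "model_tests.csv", h)
    results["curves"] = curves_df
    results["ratios"] = ratios_df
    results["tests"] = tests_df
    logger.info("model comparison done in %.1f s", time.time() - t0)
    return results


def run_group_comparison(cfg: RunConfig) -> dict:
    """Contrast subject groups (first group = reference): entropy curves,
    ratios, per-τ test tables and steady-state node tables."""
    t0 = time.time()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = cfg.config_hash()
    taus = cfg.taus
    subjects = _load_subjects(cfg)
    group_order = list(dict.fromkeys(label for label, _ in subjects))
    if len(group_order) < 2:
        raise ValueError("group comparison needs at least two groups")
    counts = {g: sum(1 for lab, _ in subjects if lab == g) for g in group_order}
    thin = [g for g, c in counts.items() if c < 2]
    if thin:
        raise ValueError(f"groups with fewer than two subjects: {thin}")

    root = np.random.SeedSequence(cfg.seed)
    graphs = _binarized_graphs(subjects, cfg, root.spawn(len(subjects)))
    n_nodes = int(np.median([d[0].n_nodes for _, d in graphs]))
    ref = group_order[0]
    results: dict = {"taus": taus, "config_hash": h, "reference": ref}
    curve_rows, test_frames, ratio_frames = [], [], []
    steady_frames = []
    for kname in cfg.walks:
        kind = WalkKind(kname)
        labels, curves = _subject_curves(graphs, kind, taus)
        by_group: dict[str, list[EntropyCurve]] = {g: [] for g in group_order}
        for lab, c in zip(labels, curves):
            by_group[lab].append(c)
        mats = {g: np.vstack([c.S for c in cs]) for g, cs in by_group.items()}
        for g in group_order:
            curve_rows.append(
                pd.DataFrame(
                    {
                        "tau": taus,
                        "value": mats[g].mean(axis=0),
                        "sd": mats[g].std(axis=0, ddof=1),
                        "group": g,
                        "walk_kind": kind.value,
                    }
                )
            )
            if g != ref:
                ratio = entropic_ratio(by_group[g], by_group[ref])
                ratio["group"] = g
                ratio["walk_kind"] = kind.value
                ratio_frames.append(ratio)
        tests = per_tau_tests(
            {g: mats[g] for g in group_order if g != ref},
            mats[ref],
            taus,
            n_nodes,
            family_across_tau=cfg.holm_family_across_tau,
        )
        tests["walk_kind"] = kind.value
        test_frames.append(tests)
        # steady-state brain-map surrogate: average stationary vectors over
        # each group's binarized subjects (full-size subjects only, so node
        # identities align)
        for g in group_order:
            vecs, lab_ref = [], None
            for lab, draws in graphs:
                if lab != g:
                    continue
                for gr in draws:
                    if gr.n_nodes != n_nodes:
                        continue
                    vecs.append(walk_system(gr, kind).pi)
                    lab_ref = gr.node_labels
            if not vecs:
                continue
            steady_frames.append(
                pd.DataFrame(
                    {
                        "label": list(lab_ref),
                        "pi": np.mean(vecs, axis=0),
                        "group": g,
                        "walk_kind": kind.value,
                    }
                )
            )
        results[f"group_samples_{kind.value}"] = mats

    curves_df = pd.concat(curve_rows, ignore_index=True)
    tests_df = pd.concat(test_frames, ignore_index=True)
    ratios_df = pd.concat(ratio_frames, ignore_index=True)
    steady_df = pd.concat(steady_frames, ignore_index=True)
    _write_csv(curves_df, outdir / "group_entropy_curves.csv", h)
    _write_csv(ratios_df, outdir / "group_entropic_ratios.csv", h)
    _write_csv(tests_df, outdir / "group_tests.csv", h)
    _write_csv(steady_df, outdir / "steady_state_maps.csv", h)
    results.update(
        curves=curves_df, ratios=ratios_df, tests=tests_df, steady=steady_df
    )
    logger.info("group comparison done in %.1f s", time.time() - t0)
    return results
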