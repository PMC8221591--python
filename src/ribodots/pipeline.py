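"""End-to-end orchestration: simulate -> quantify -> test -> report.

Two pipelines mirror the study's two arms.  ``run_trap_pipeline`` simulates
(or accepts) a CT table, selects the housekeeping pair, and emits a
publication-style fold-change table (per-gene group dCT means +- SEM, log2
fold change with propagated SE, raw and Holm–Sidak-adjusted p) plus the
stability report and the pair's own ratio/fold-change check.
``run_insitu_pipeline`` simulates two groups of scenes with a designed effect
on one channel, quantifies each with :class:`~ribodots.insitu.DotQuantifier`,
and tests group differences in dot density per (region x roi_class x
channel).  Figure-style outputs are tidy CSV tables; both pipelines are
deterministic under a fixed seed and record a run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import qpcr
from .insitu import DotQuantifier
from .simulate import (
    CtPanel,
    SceneParams,
    default_panel,
    simulate_ct_table,
    simulate_scene,
)

__all__ = ["RunManifest", "run_trap_pipeline", "run_insitu_pipeline"]


@dataclass
class RunManifest:
    """What a run did: config hash, seed, outputs and their row counts."""

    config: dict
    seed: int
    software: str = "ribodots 0.1.0"
    outputs: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["config_hash"] = self.config_hash
        return json.dumps(d, indent=2, sort_keys=True, default=str)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def run_trap_pipeline(
    panel: CtPanel | None = None,
    table: pd.DataFrame | None = None,
    n_per_group: int | tuple[int, int] = (4, 5),
    seed: int = 0,
    alpha: float = 0.05,
    top_k: int = 4,
) -> dict:
    """Reference-gene selection plus per-gene ddCT report on one CT table.

    Returns a dict with ``stability`` (per-gene stability report),
    ``fold_changes`` (per-target report table), ``pair_check`` (selected pair
    ratio and signed fold change), ``delta_ct`` (per-sample dCT) and
    ``manifest``.
    """
    p = panel if panel is not None else default_panel()
    if table is None:
        table, _truth = simulate_ct_table(p, n_per_group=n_per_group, seed=seed)
    candidates = [g.name for g in p.genes if g.role == "reference"]
    targets = [g.name for g in p.genes if g.role == "target"]

    selector = qpcr.ReferenceGeneSelector(candidate_genes=candidates, top_k=top_k)
    dct = selector.fit_transform(table)
    dct = dct[dct["gene"].isin(targets)]

    rows = []
    for gene in targets:
        sub = dct[dct["gene"] == gene]
        a = sub.loc[sub["group"] == "sleep", "dCT"].to_numpy()
        b = sub.loc[sub["group"] == "SD", "dCT"].to_numpy()
        fc = qpcr.ddct_fold_change(a, b)
        t, df, praw = qpcr.group_test(a, b)
        rows.append(
            {
                "gene": gene,
                "sleep_dct_mean": a.mean(),
                "sleep_dct_sem": a.std(ddof=1) / np.sqrt(len(a)),
                "sd_dct_mean": b.mean(),
                "sd_dct_sem": b.std(ddof=1) / np.sqrt(len(b)),
                "ddct": fc.ddct,
                "log2_fc": fc.log2_fc,
                "log2_fc_se": fc.se,
                "ratio": fc.ratio,
                "fold_change": round(fc.fold_change, 2),
                "t": t, "df": df, "p_raw": praw,
                "n_sleep": len(a), "n_sd": len(b),
            }
        )
    report = pd.DataFrame(rows)
    p_adj, reject = qpcr.holm_sidak(report["p_raw"].to_numpy(), alpha=alpha)
    report["p_adj"] = p_adj
    report["significant"] = reject

    pair_check = pd.DataFrame(
        [
            {
                "pair": "/".join(selector.selected_pair_),
                "ratio": selector.pair_ratio_,
                "fold_change": round(selector.pair_fold_change_, 2),
            }
        ]
    )
    manifest = RunManifest(
        config={
            "panel": [dataclasses.asdict(g) for g in p.genes],
            "n_per_group": n_per_group, "alpha": alpha, "top_k": top_k,
        },
        seed=seed,
        outputs={
            "stability": len(selector.stability_),
            "fold_changes": len(report),
            "delta_ct": len(dct),
        },
    )
    return {
        "stability": selector.stability_.reset_index(),
        "selected_pair": selector.selected_pair_,
        "pair_check": pair_check,
        "delta_ct": dct,
        "fold_changes": report,
        "manifest": manifest,
    }


def run_insitu_pipeline(
    n_sleep: int = 5,
    n_sd: int = 6,
    base_params: SceneParams | None = None,
    effect_channel: str = "Arc",
    effect_fold: float = 3.0,
    seed: int = 0,
    alpha: float = 0.05,
    quantifier_kwargs: dict | None = None,
) -> dict:
    """Two-group synthetic in-situ experiment with group statistics.

    Sleep-group scenes use ``base_params``; sleep-deprived scenes carry
    ``effect_fold`` times as many dots on ``effect_channel``.  Each scene is
    quantified independently; dot densities are compared per (region x
    roi_class x channel) with a Welch t, Holm–Sidak-corrected within each
    region x roi_class family.
    """
    base = base_params if base_params is not None else SceneParams(
        shape=(512, 512), n_dots=60, n_cells=8
    )
    qkw = quantifier_kwargs or {}
    rng = np.random.default_rng(seed)

    roi_rows, overlap_rows, cell_rows = [], [], []
    warnings_log: list[str] = []
    for group, n in (("sleep", n_sleep), ("SD", n_sd)):
        for i in range(n):
            p = dataclasses.replace(base)
            if group == "SD":
                p = dataclasses.replace(
                    base, n_dots=int(round(base.n_dots * effect_fold))
                )
            scene_seed = int(rng.integers(0, 2**31 - 1))
            scene, truth = simulate_scene(p, seed=scene_seed)
            quant = DotQuantifier(**qkw).fit(scene)
            t = quant.transform()
            t["group"], t["animal"] = group, f"{group}_{i + 1}"
            roi_rows.append(t)
            ov = quant.overlap_table()
            ov["group"], ov["animal"] = group, f"{group}_{i + 1}"
            overlap_rows.append(ov)
            if hasattr(quant, "cell_intensity_"):
                ci = quant.cell_intensity_table()
                ci["group"], ci["animal"] = group, f"{group}_{i + 1}"
                cell_rows.append(ci)
            warnings_log.extend(quant.warnings_)

    roi = pd.concat(roi_rows, ignore_index=True)
    overlap = pd.concat(overlap_rows, ignore_index=True)
    cells = pd.concat(cell_rows, ignore_index=True) if cell_rows else pd.DataFrame()

    tests = []
    for (region, roi_class), fam in roi.groupby(["region", "roi_class"]):
        fam_rows = []
        for channel, sub in fam.groupby("channel"):
            a = sub.loc[sub["group"] == "sleep", "dots_per_area"].dropna().to_numpy()
            b = sub.loc[sub["group"] == "SD", "dots_per_area"].dropna().to_numpy()
            if len(a) < 2 or len(b) < 2:
                warnings_log.append(
                    f"contrast {region}/{roi_class}/{channel} lacks samples"
                )
                continue
            t, df, praw = qpcr.group_test(a, b)
            fam_rows.append(
                {
                    "region": region, "roi_class": roi_class, "channel": channel,
                    "sleep_mean": a.mean(), "sd_mean": b.mean(),
                    "t": t, "df": df, "p_raw": praw,
                    "n_sleep": len(a), "n_sd": len(b),
                }
            )
        if fam_rows:
            fam_df = pd.DataFrame(fam_rows)
            p_adj, reject = qpcr.holm_sidak(fam_df["p_raw"].to_numpy(), alpha=alpha)
            fam_df["p_adj"], fam_df["significant"] = p_adj, reject
            tests.append(fam_df)
    tests_df = (
        pd.concat(tests, ignore_index=True) if tests else pd.DataFrame()
    )

    manifest = RunManifest(
        config={
            "base_params": dataclasses.asdict(base),
            "n_sleep": n_sleep, "n_sd": n_sd,
            "effect_channel": effect_channel, "effect_fold": effect_fold,
            "alpha": alpha, "quantifier": qkw,
        },
        seed=seed,
        outputs={"roi": len(roi), "overlap": len(overlap), "tests": len(tests_df)},
        warnings=warnings_log,
    )
    return {
        "roi": roi,
        "overlap": overlap,
        "cell_intensity": cells,
        "tests": tests_df,
        "manifest": manifest,
    }


def write_outputs(result: dict, out_dir: str | Path) -> None:
    """Write every DataFrame of a pipeline result as CSV plus the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, obj in result.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out / f"{name}.csv", index=False)
    manifest = result.get("manifest")
    if isinstance(manifest, RunManifest):
        manifest.write(out / "manifest.json")
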