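"""End-to-end orchestration: synthetic study -> tables -> report.

``run_pipeline`` sequences the full analysis on either a synthetic dataset
(generated under the configured conditions) or user-supplied inputs:
structure traits from voxel bones, GPA and centroid size, ecotype tests on
ln size, shape models (Pillai MANOVA on PC scores, Procrustes ANCOVA with
and without the phylogenetic transform, pairwise ecotype tests), the
five-model PGLS competition per structure trait with bootstrap confidence
intervals and allometry verdicts, two-block PLS between shape and structure
and between the two bones, CVA with jackknife cross-validation, and
phylogenetic paired t-tests between bones.

Every stochastic stage draws its seed from the master seed through a stable
stage label, so adding or removing a stage never perturbs the randomness of
the others, and a fixed seed yields byte-identical report tables.  Stage
failures are isolated: a failed stage is recorded in the manifest and the
run continues.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import morphometrics as mm
from . import phylo as ph
from . import structure as st
from . import synthetic as syn

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "validate_inputs",
           "make_report", "stage_seed"]

BONES = ("humerus", "femur")
TRAITS = ("Cg", "DE", "CSS")


def stage_seed(master: int, label: str) -> np.random.SeedSequence:
    """Stage-scoped seed: master seed + stable hash of the stage label."""
    h = int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "big")
    return np.random.SeedSequence([int(master), h])


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    seed: int
    out_dir: str = "limbmorph_run"
    synthetic: bool = True
    n_tips: int = 76
    n_perm: int = 1000
    n_boot: int = 1000
    fraction: float = 0.40
    voxel_spacing: float = 0.5
    stages: tuple[str, ...] = ("structure", "shape", "models", "pls", "cva",
                               "paired")
    # paths for user data (ignored in synthetic mode)
    tree_path: str | None = None
    specimen_table: str | None = None
    landmark_dir: str | None = None
    volume_dir: str | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0.0 < self.fraction < 1.0):
            raise ValueError("fraction must lie in (0, 1)")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def config_hash(self) -> str:
        d = asdict(self)
        d["stages"] = list(d["stages"])
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All tables of one run plus the reproducibility manifest."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def add(self, name: str, df: pd.DataFrame) -> None:
        self.tables[name] = df


def validate_inputs(tree: ph.Phylogeny, specimens: pd.DataFrame,
                    shapes: dict[str, dict] | dict | None = None,
                    volumes: dict | None = None,
                    interaction_min: int = 2) -> pd.DataFrame:
    """Cross-check tree tips against the specimen table and data files.

    Always returns a report DataFrame (columns: severity, kind, detail);
    an empty frame means a consistent dataset.  Duplicated specimen ids are
    fatal; tips missing from any supplied source are reported as orphans in
    both directions; ecotypes with fewer than ``interaction_min`` members
    are flagged because the size-by-ecotype interaction model needs them.
    """
    problems: list[dict] = []
    ids = list(specimens["species"])
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        problems.append({"severity": "fatal", "kind": "duplicate_specimen",
                         "detail": ",".join(map(str, dupes))})
    tips = set(tree.tip_labels)
    tab = set(ids)
    for orphan in sorted(tips - tab):
        problems.append({"severity": "error", "kind": "tip_without_specimen",
                         "detail": orphan})
    for orphan in sorted(tab - tips):
        problems.append({"severity": "error", "kind": "specimen_without_tip",
                         "detail": orphan})
    for name, src in (("landmarks", shapes), ("volume", volumes)):
        if src is None:
            continue
        have = set(src)
        for orphan in sorted(tab - have):
            problems.append({"severity": "error",
                             "kind": f"specimen_without_{name}",
                             "detail": orphan})
        for orphan in sorted(have - tab):
            problems.append({"severity": "warning",
                             "kind": f"{name}_without_specimen",
                             "detail": orphan})
    if "ecotype" in specimens.columns:
        counts = specimens["ecotype"].value_counts()
        for eco, c in counts.items():
            if c < interaction_min:
                problems.append({
                    "severity": "warning", "kind": "small_ecotype",
                    "detail": f"{eco}: {c} tips (interaction model needs "
                              f">= {interaction_min})"})
    return pd.DataFrame(problems, columns=["severity", "kind", "detail"])


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _synthesize(config: RunConfig) -> dict:
    """Build the two-bone synthetic study sharing one tree and ecotypes."""
    master = config.seed
    rng_tree = np.random.default_rng(stage_seed(master, "tree"))
    tree = syn.simulate_phylogeny(config.n_tips, rng_tree)
    eco = syn.assign_clustered_ecotypes(
        tree, seed=np.random.default_rng(stage_seed(master, "ecotypes")))
    bones = {}
    for bone in BONES:
        params = syn.EvolParams(n_tips=config.n_tips)
        rng = np.random.default_rng(stage_seed(master, f"traits:{bone}"))
        lnsize = syn.simulate_lnsize(tree, params, rng)
        traits = syn.simulate_traits(tree, eco, params, rng, lnsize=lnsize)
        shapes, truth = syn.simulate_shapes(tree, eco, params, rng,
                                            lnsize=lnsize)
        bones[bone] = {"traits": traits, "shapes": shapes, "truth": truth}
    specimens = pd.DataFrame({"species": tree.tip_labels,
                              "ecotype": eco.loc[tree.tip_labels].to_numpy()})
    return {"tree": tree, "ecotypes": eco, "specimens": specimens,
            "bones": bones}


def _voxel_bones(data: dict, config: RunConfig) -> dict[str, dict[str, st.VoxelVolume]]:
    vols: dict[str, dict] = {}
    spacing = config.voxel_spacing
    for bone in BONES:
        traits = data["bones"][bone]["traits"]
        vols[bone] = {}
        for tip in data["tree"].tip_labels:
            row = traits.loc[tip]
            scale = float(np.exp(0.3 * (row["lnsize"] - 4.0)))
            css = float(np.clip(row["CSS"], 1.0, 4.0))
            b = 3.0 * scale
            h = min(spacing, b / 5.5)  # resolve the smallest shafts too
            spec = syn.BoneSpec(length=40.0 * scale,
                                a_mid=b * np.sqrt(css), b_mid=b,
                                thickness=max(1.2 * scale, 2.5 * h))
            vol, _ = syn.make_synthetic_bone(spec, h)
            vols[bone][tip] = vol
    return vols


def run_pipeline(config: RunConfig,
                 dataset: dict | None = None) -> ReportBundle:
    """Execute the configured stages and collect every result table.

    ``dataset`` can inject a pre-built study (as returned by the synthetic
    builder); otherwise one is synthesized from the config.  Stage failures
    are recorded in ``bundle.manifest['stage_status']`` and do not abort the
    run.
    """
    bundle = ReportBundle()
    status: dict[str, str] = {}
    master = config.seed

    if dataset is None:
        if not config.synthetic:
            dataset = _load_user_data(config)
        else:
            dataset = _synthesize(config)
    tree: ph.Phylogeny = dataset["tree"]
    specimens: pd.DataFrame = dataset["specimens"]
    eco = dataset["ecotypes"]

    bundle.add("specimens", specimens.copy())
    report = validate_inputs(tree, specimens)
    bundle.add("validation", report)

    # --- structure traits from voxel bones --------------------------------
    if "structure" in config.stages:
        try:
            vols = _voxel_bones(dataset, config)
            frames = []
            for bone in BONES:
                manifest = pd.DataFrame({
                    "specimen": tree.tip_labels,
                    "bone": bone,
                })
                tab = st.batch_structure(manifest, config.fraction,
                                         volumes=vols[bone])
                frames.append(tab)
            measured = pd.concat(frames, ignore_index=True)
            bundle.add("structure_measured", measured)
            status["structure"] = "ok"
        except Exception as exc:  # noqa: BLE001
            status["structure"] = f"failed: {exc}"

    # --- GPA / centroid size / size tests ---------------------------------
    aligned: dict[str, mm.AlignedSample] = {}
    lnsize_gpa: dict[str, pd.Series] = {}
    try:
        size_rows = []
        for bone in BONES:
            sample = mm.LandmarkSample.from_dict(dataset["bones"][bone]["shapes"])
            al = mm.gpa(sample)
            aligned[bone] = al
            lncs = pd.Series(np.log(al.centroid_sizes),
                             index=al.specimen_ids, name="lnsize")
            lnsize_gpa[bone] = lncs
            fit = ph.phylo_anova(lncs.loc[tree.tip_labels].to_numpy(),
                                 eco.loc[tree.tip_labels], tree)
            size_rows.append({"bone": bone, "r2": fit.r2, "lambda": fit.lam,
                              "loglik": fit.loglik})
        bundle.add("size_anova", pd.DataFrame(size_rows))
        status["gpa"] = "ok"
    except Exception as exc:  # noqa: BLE001
        status["gpa"] = f"failed: {exc}"

    # --- shape models ------------------------------------------------------
    if "shape" in config.stages and aligned:
        for bone in BONES:
            try:
                al = aligned[bone]
                order = [al.specimen_ids.index(t) for t in tree.tip_labels]
                Y = al.flat()[order]
                data = pd.DataFrame(
                    {"lnsize": lnsize_gpa[bone].loc[tree.tip_labels],
                     "ecotype": eco.loc[tree.tip_labels]},
                    index=tree.tip_labels)
                seed_np = stage_seed(master, f"shape:{bone}")
                n = Y.shape[0]
                g = data["ecotype"].nunique()
                max_pc = max(2, min(12, n - 2 * g - 3))
                scores = _shape_pc_scores_from(Y, max_pc)
                man = mm.pillai_manova(scores, data, "~ lnsize + ecotype",
                                       n_perm=config.n_perm, seed=seed_np)
                man.insert(0, "bone", bone)
                bundle.add(f"shape_manova_{bone}", man)
                for label, kw in (("none", {}), ("bm", {"phylo": "bm",
                                                        "tree": tree})):
                    fitm = mm.procrustes_lm(
                        Y, data, "~ lnsize + ecotype", n_perm=config.n_perm,
                        seed=stage_seed(master, f"ancova:{bone}:{label}"),
                        **kw)
                    tab = fitm.table.copy()
                    tab.insert(0, "phylo", label)
                    tab.insert(0, "bone", bone)
                    bundle.add(f"shape_ancova_{bone}_{label}", tab)
                    if label == "none":
                        pw = mm.pairwise_groups(
                            fitm, "ecotype", n_perm=config.n_perm,
                            seed=stage_seed(master, f"pairwise:{bone}"))
                        pw.insert(0, "bone", bone)
                        bundle.add(f"shape_pairwise_{bone}", pw)
                status[f"shape:{bone}"] = "ok"
            except Exception as exc:  # noqa: BLE001
                status[f"shape:{bone}"] = f"failed: {exc}"

    # --- structure-trait model competition + bootstrap allometry ----------
    if "models" in config.stages:
        for bone in BONES:
            traits = dataset["bones"][bone]["traits"]
            for trait in TRAITS:
                key = f"{bone}:{trait}"
                try:
                    y = traits[trait].loc[tree.tip_labels].to_numpy()
                    x = traits["lnsize"].loc[tree.tip_labels].to_numpy()
                    comp = ph.fit_model_set(y, x, eco.loc[tree.tip_labels],
                                            tree)
                    tab = comp.table.copy()
                    tab.insert(0, "trait", trait)
                    tab.insert(0, "bone", bone)
                    bundle.add(f"models_{bone}_{trait}", tab)

                    fit_int = comp.fits["size*ecotype"]
                    ens = ph.bootstrap_coefficients(
                        fit_int, n_boot=config.n_boot,
                        seed=stage_seed(master, f"boot:{key}"))
                    calls = []
                    call = ph.slope_ci(ens)
                    calls.append({"bone": bone, "trait": trait,
                                  "ecotype": "all", "slope": call.slope,
                                  "ci_low": call.ci_low,
                                  "ci_high": call.ci_high,
                                  "verdict": call.verdict})
                    for lev in sorted(eco.unique()):
                        call = ph.slope_ci(ens, group=lev)
                        calls.append({"bone": bone, "trait": trait,
                                      "ecotype": lev, "slope": call.slope,
                                      "ci_low": call.ci_low,
                                      "ci_high": call.ci_high,
                                      "verdict": call.verdict})
                    bundle.add(f"allometry_{bone}_{trait}",
                               pd.DataFrame(calls))
                    for qty in ("means", "slopes"):
                        pw = ph.pairwise_ci(ens, qty)
                        pw.insert(0, "quantity", qty)
                        pw.insert(0, "trait", trait)
                        pw.insert(0, "bone", bone)
                        bundle.add(f"pairwise_{qty}_{bone}_{trait}", pw)
                    status[f"models:{key}"] = "ok"
                except Exception as exc:  # noqa: BLE001
                    status[f"models:{key}"] = f"failed: {exc}"

    # --- two-block PLS ------------------------------------------------------
    if "pls" in config.stages and aligned:
        try:
            rows = []
            for bone in BONES:
                al = aligned[bone]
                order = [al.specimen_ids.index(t) for t in tree.tip_labels]
                Y = al.flat()[order]
                traits = dataset["bones"][bone]["traits"]
                for trait in TRAITS:
                    res = mm.two_block_pls(
                        Y, traits[trait].loc[tree.tip_labels].to_numpy(),
                        n_perm=config.n_perm,
                        seed=stage_seed(master, f"pls:{bone}:{trait}"))
                    rows.append({"block_x": f"{bone} shape",
                                 "block_y": f"{bone} {trait}",
                                 "r_pls": res.r_pls, "z": res.z, "p": res.p})
            Yh = aligned["humerus"].flat()[
                [aligned["humerus"].specimen_ids.index(t)
                 for t in tree.tip_labels]]
            Yf = aligned["femur"].flat()[
                [aligned["femur"].specimen_ids.index(t)
                 for t in tree.tip_labels]]
            res = mm.two_block_pls(Yh, Yf, n_perm=config.n_perm,
                                   seed=stage_seed(master, "pls:bones"))
            rows.append({"block_x": "humerus shape", "block_y": "femur shape",
                         "r_pls": res.r_pls, "z": res.z, "p": res.p})
            bundle.add("pls", pd.DataFrame(rows))
            status["pls"] = "ok"
        except Exception as exc:  # noqa: BLE001
            status["pls"] = f"failed: {exc}"

    # --- CVA ----------------------------------------------------------------
    if "cva" in config.stages and aligned:
        try:
            rows = []
            for bone in BONES:
                al = aligned[bone]
                order = [al.specimen_ids.index(t) for t in tree.tip_labels]
                res = mm.cva_jackknife(al.flat()[order],
                                       eco.loc[tree.tip_labels])
                row = {"bone": bone, "overall_accuracy": res.overall_accuracy,
                       "retained_dims": res.retained_dims}
                for lev, acc in res.group_accuracy.items():
                    row[f"accuracy_{lev}"] = acc
                rows.append(row)
            bundle.add("cva", pd.DataFrame(rows))
            status["cva"] = "ok"
        except Exception as exc:  # noqa: BLE001
            status["cva"] = f"failed: {exc}"

    # --- phylogenetic paired t-tests humerus vs femur ----------------------
    if "paired" in config.stages:
        try:
            rows = []
            th = dataset["bones"]["humerus"]["traits"]
            tf = dataset["bones"]["femur"]["traits"]
            for trait in TRAITS:
                res = ph.phylo_paired_ttest(
                    th[trait].loc[tree.tip_labels].to_numpy(),
                    tf[trait].loc[tree.tip_labels].to_numpy(), tree)
                rows.append({"trait": trait,
                             "mean_difference": res.mean_difference,
                             "se": res.se, "t": res.t, "p": res.p,
                             "lambda": res.lam})
            bundle.add("paired_ttests", pd.DataFrame(rows))
            status["paired"] = "ok"
        except Exception as exc:  # noqa: BLE001
            status["paired"] = f"failed: {exc}"

    bundle.manifest = {
        "config_hash": config.config_hash(),
        "seed": int(master),
        "n_perm": config.n_perm,
        "n_boot": config.n_boot,
        "software_version": _version(),
        "stage_status": status,
    }
    return bundle


def _shape_pc_scores_from(Y: np.ndarray, max_dims: int) -> np.ndarray:
    pca = mm.shape_pca(Y)
    m = min(max_dims, pca.scores.shape[1])
    return pca.scores[:, :m]


def _version() -> str:
    from . import __version__

    return __version__


def _load_user_data(config: RunConfig) -> dict:
    """Assemble a dataset dict from on-disk inputs (non-synthetic mode)."""
    if config.tree_path is None or config.specimen_table is None:
        raise ValueError("non-synthetic runs need tree_path and specimen_table")
    tree = ph.Phylogeny.from_newick(config.tree_path)
    specimens = pd.read_csv(config.specimen_table)
    eco = specimens.set_index("species")["ecotype"]
    bones: dict[str, dict] = {}
    for bone in BONES:
        entry: dict = {"traits": None, "shapes": {}}
        if config.landmark_dir:
            lmdir = Path(config.landmark_dir) / bone
            if lmdir.exists():
                for f in sorted(lmdir.glob("*.csv")):
                    s = mm.read_landmarks(f)
                    for i, sid in enumerate(s.specimen_ids):
                        entry["shapes"][sid] = s.coords[i]
        bones[bone] = entry
    return {"tree": tree, "ecotypes": eco, "specimens": specimens,
            "bones": bones}


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def make_report(bundle: ReportBundle, out_dir, fmt: str = "md") -> list[Path]:
    """Write every table as CSV plus a human-readable summary and manifest.

    Returns the list of files written.  Numbers in the summary are read back
    from the CSV frames, so re-rendering from saved tables is byte-stable.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_test"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise ValueError(f"unwritable output directory: {out}") from exc

    written: list[Path] = []
    for name, df in sorted(bundle.tables.items()):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        written.append(p)
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(bundle.manifest, indent=2, sort_keys=True))
    written.append(mpath)

    lines = ["# limbmorph run summary", ""]
    if not bundle.tables:
        lines.append("No stages ran: the bundle is empty.")
    else:
        model_tables = [n for n in sorted(bundle.tables) if n.startswith("models_")]
        if model_tables:
            lines.append("## Model competition (per bone x trait)")
            lines.append("")
            for name in model_tables:
                df = bundle.tables[name]
                best = df.iloc[0]
                lines.append(
                    f"- **{best['bone']} {best['trait']}**: best model "
                    f"`{best['model']}` (AICw = {best['aicw']:.2f}, "
                    f"R2 = {best['r2']:.2f}, lambda = {best['lambda']:.2f})")
            lines.append("")
        allo = [n for n in sorted(bundle.tables) if n.startswith("allometry_")]
        if allo:
            lines.append("## Allometry verdicts")
            lines.append("")
            for name in allo:
                for _, r in bundle.tables[name].iterrows():
                    lines.append(
                        f"- {r['bone']} {r['trait']} [{r['ecotype']}]: "
                        f"{r['verdict']} (slope {r['slope']:.3f} "
                        f"[{r['ci_low']:.3f}:{r['ci_high']:.3f}])")
            lines.append("")
        if "cva" in bundle.tables:
            lines.append("## CVA jackknife reclassification")
            lines.append("")
            for _, r in bundle.tables["cva"].iterrows():
                lines.append(f"- {r['bone']}: overall "
                             f"{r['overall_accuracy']:.1f}% accuracy")
            lines.append("")
        if "pls" in bundle.tables:
            lines.append("## Two-block PLS")
            lines.append("")
            for _, r in bundle.tables["pls"].iterrows():
                lines.append(f"- {r['block_x']} vs {r['block_y']}: "
                             f"r-PLS = {r['r_pls']:.2f} (p = {r['p']:.4g})")
            lines.append("")
    spath = out / ("summary.md" if fmt == "md" else "summary.html")
    text = "\n".join(lines) + "\n"
    if fmt == "html":
        text = "<pre>\n" + text + "</pre>\n"
    spath.write_text(text)
    written.append(spath)
    return written
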