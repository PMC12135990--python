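"""Project-directory pipeline: the stage sequence as a library.

Mirrors the interactive workflow as a series of resumable stages, each
reading the previous stage's artifacts from a project directory and
writing its own (CSV curves, multi-model PDB pools, JSON reports, a plain
text log).  Stages:

    load-saxs       read + unit-convert experimental I(q) and P(r)
    load-structure  read the structure; starting-model P(r)/I(q) fit
    flex            detect (or accept manual) flexible regions
    mc              torsion Monte Carlo conformer pool
    reduce          stride/offset reduction + Rg histogram check
    profiles        per-model P(r) and I(q) on the experimental grids
    select          NNLS preselection against I(q) and P(r)
    final           adjacent-frame augmentation + final NNLS + report

Everything is seeded through the config, so rerunning any stage with
unchanged inputs reproduces its outputs byte for byte.
"""

from __future__ import annotations

import csv
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import yaml

from . import ensemble, pool as pool_ops
from .mc import MCConfig, run_mc
from .profiles import (
    PofR,
    ScatteringCurve,
    compute_iq_debye,
    compute_pr,
    convert_units,
    interpolate_to_grid,
    load_curve_text,
    pr_on_grid,
    rg_from_coords,
    rg_from_pr,
    scale_and_chi2,
)
from .regions import FlexibleRegion, detect_flexible_regions, parse_region, validate_alignment_range
from .structure import ConformerPool, read_multimodel_pdb, read_structure, write_multimodel_pdb

__all__ = ["ProjectConfig", "STAGES", "run_stage", "run_all", "final_report", "register_calculator"]

STAGES = [
    "load-saxs",
    "load-structure",
    "flex",
    "mc",
    "reduce",
    "profiles",
    "select",
    "final",
]

_PREREQUISITES: dict[str, list[str]] = {
    "load-saxs": [],
    "load-structure": ["load-saxs"],
    "flex": ["load-structure"],
    "mc": ["flex"],
    "reduce": ["mc"],
    "profiles": ["reduce"],
    "select": ["profiles"],
    "final": ["select"],
}

_STAGE_MARKER: dict[str, str] = {
    "load-saxs": "iq_exp.csv",
    "load-structure": "structure_params.json",
    "flex": "regions.json",
    "mc": "pool.pdb",
    "reduce": "reduced.pdb",
    "profiles": "model_iq.csv",
    "select": "preselection.json",
    "final": "final.json",
}


# pluggable I(q) calculators: name -> fn(structure, q_grid) -> ScatteringCurve
_CALCULATORS: dict[str, Callable] = {
    "debye": lambda s, q: compute_iq_debye(s, q, mode="point"),
    "debye-cm": lambda s, q: compute_iq_debye(s, q, mode="cromer_mann"),
}


def register_calculator(name: str, fn: Callable) -> None:
    """Register an external I(q) calculator behind the standard contract.

    ``fn(structure, q_grid) -> ScatteringCurve``; its output passes through
    the same interpolation and scaling steps as the internal calculator.
    """
    _CALCULATORS[name] = fn


@dataclass
class ProjectConfig:
    """Flat configuration for one project (serializable to YAML)."""

    project_name: str
    structure_path: str = ""
    iq_path: str = ""
    pr_path: str = ""
    q_unit: str = "inv_angstrom"
    r_unit: str = "angstrom"
    auto_flex: bool = True
    flex_threshold: float = 60.0
    flex_min_run: int = 5
    manual_regions: list[str] = field(default_factory=list)
    align_range: str = ""  # "start:end"; empty -> largest rigid stretch
    trial_attempts: int = 50000
    max_angle: float = 30.0
    temperature: float = 300.0
    return_after_fails: int = 20
    overlap_basis: str = "heavy"
    stride: int = 10
    offset: int = 0
    calculator: str = "debye"
    adjacent_k: int = 0
    use_sd_weighting_iq: bool = True
    pr_sd_weighting: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.project_name:
            raise ValueError("project_name must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProjectConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def project_dir(self, workdir: str | Path = ".") -> Path:
        return Path(workdir) / self.project_name


# ---------------------------------------------------------------------------
# small artifact helpers


def _write_table(path: Path, header: list[str], columns: list[np.ndarray]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for row in zip(*columns):
            writer.writerow([f"{v:.12e}" for v in row])


def _read_table(path: Path) -> tuple[list[str], np.ndarray]:
    with open(path) as fh:
        reader = csv.reader(fh)
        header = next(reader)
        data = np.array([[float(v) for v in row] for row in reader])
    return header, data


def _log(project: Path, stage: str, message: str) -> None:
    stamp = time.strftime("%Y-%m-%d %H:%M:%S")
    with open(project / "project.log", "a") as fh:
        fh.write(f"[{stamp}] [{stage}] {message}\n")


def _require(project: Path, stage: str) -> None:
    for prereq in _PREREQUISITES[stage]:
        if not (project / _STAGE_MARKER[prereq]).exists():
            raise RuntimeError(
                f"stage '{stage}' needs outputs of stage '{prereq}'; "
                f"run '{prereq}' first"
            )


def _load_exp_iq(project: Path) -> ScatteringCurve:
    _, data = _read_table(project / "iq_exp.csv")
    sd = data[:, 2] if data.shape[1] > 2 else None
    return ScatteringCurve(data[:, 0], data[:, 1], sd)


def _load_exp_pr(project: Path) -> PofR:
    _, data = _read_table(project / "pr_exp.csv")
    sd = data[:, 2] if data.shape[1] > 2 else None
    return PofR(data[:, 0], data[:, 1], sd)


def _load_regions(project: Path) -> list[FlexibleRegion]:
    data = json.loads((project / "regions.json").read_text())
    return [FlexibleRegion(r["start"], r["end"]) for r in data["regions"]]


def _resolve_align_range(config: ProjectConfig, regions, n_residues: int) -> FlexibleRegion:
    if config.align_range:
        rng = parse_region(config.align_range)
    else:
        # largest stretch free of flexible regions
        flexible = set()
        for r in regions:
            flexible.update(range(r.start, r.end + 1))
        best, cur_start = None, None
        for i in range(1, n_residues + 2):
            if i <= n_residues and i not in flexible:
                if cur_start is None:
                    cur_start = i
            else:
                if cur_start is not None:
                    cand = FlexibleRegion(cur_start, i - 1)
                    if best is None or len(cand) > len(best):
                        best = cand
                    cur_start = None
        if best is None:
            raise ValueError("no rigid residues available for alignment")
        rng = best
    validate_alignment_range(regions, rng, n_residues)
    return rng


# ---------------------------------------------------------------------------
# stages


def run_stage(config: ProjectConfig, stage: str, workdir: str | Path = ".") -> Path:
    """Execute one pipeline stage, writing artifacts to the project dir.

    Raises ``RuntimeError`` naming the stage to run first when a
    prerequisite's outputs are missing.  Returns the project directory.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; stages are {STAGES}")
    project = config.project_dir(workdir)
    project.mkdir(parents=True, exist_ok=True)
    _require(project, stage)
    handler = {
        "load-saxs": _stage_load_saxs,
        "load-structure": _stage_load_structure,
        "flex": _stage_flex,
        "mc": _stage_mc,
        "reduce": _stage_reduce,
        "profiles": _stage_profiles,
        "select": _stage_select,
        "final": _stage_final,
    }[stage]
    handler(config, project)
    return project


def run_all(config: ProjectConfig, workdir: str | Path = ".") -> Path:
    """Run every stage in sequence; returns the project directory."""
    for stage in STAGES:
        run_stage(config, stage, workdir)
    return config.project_dir(workdir)


def _stage_load_saxs(config: ProjectConfig, project: Path) -> None:
    iq = convert_units(load_curve_text(config.iq_path, "iq"), config.q_unit)
    pr = convert_units(load_curve_text(config.pr_path, "pr"), config.r_unit)
    cols = [iq.q, iq.intensity] + ([iq.sd] if iq.sd is not None else [])
    _write_table(project / "iq_exp.csv", ["q", "I", "sd"][: len(cols)], cols)
    cols = [pr.r, pr.p] + ([pr.sd] if pr.sd is not None else [])
    _write_table(project / "pr_exp.csv", ["r", "P", "sd"][: len(cols)], cols)
    _log(project, "load-saxs",
         f"loaded I(q) ({len(iq)} pts, unit {config.q_unit}) and "
         f"P(r) ({len(pr)} pts, unit {config.r_unit})")


def _stage_load_structure(config: ProjectConfig, project: Path) -> None:
    structure = read_structure(config.structure_path)
    exp_iq = _load_exp_iq(project)
    exp_pr = _load_exp_pr(project)

    calc = _CALCULATORS[config.calculator]
    calc_iq = _on_grid(calc(structure, exp_iq.q), exp_iq.q)
    iq_fit = scale_and_chi2(calc_iq, exp_iq)
    calc_pr = compute_pr(structure, bin_width=exp_pr.bin_width or 1.0)
    n_bins = max(calc_pr.r.size, exp_pr.r.size)
    grid = np.arange(n_bins) * calc_pr.bin_width
    pr_exp_padded = pr_on_grid(exp_pr, grid)
    pr_calc_padded = pr_on_grid(calc_pr, grid)
    pr_curve = ScatteringCurve(grid + 1e-12, pr_calc_padded.p)  # reuse scaler
    pr_fit = scale_and_chi2(
        pr_curve, ScatteringCurve(grid + 1e-12, pr_exp_padded.p)
    )

    params = {
        "n_atoms": len(structure),
        "n_residues": structure.n_residues,
        "molecular_mass_da": structure.molecular_mass,
        "rg_coords_a": rg_from_coords(structure),
        "rg_exp_pr_a": rg_from_pr(exp_pr),
        "mean_confidence": float(np.mean(structure.residue_confidence())),
        "iq_scale": iq_fit.scale,
        "iq_nchi2": iq_fit.nchi2,
        "iq_rmsd": iq_fit.rmsd,
        "pr_scale": pr_fit.scale,
        "pr_rmsd": pr_fit.rmsd,
        "structure_path": str(config.structure_path),
    }
    (project / "structure_params.json").write_text(json.dumps(params, indent=2))
    _write_table(project / "starting_iq.csv", ["q", "I_calc"],
                 [calc_iq.q, calc_iq.intensity])
    _write_table(project / "starting_pr.csv", ["r", "P_calc"],
                 [calc_pr.r, calc_pr.p])
    _log(project, "load-structure",
         f"{params['n_atoms']} atoms, {params['n_residues']} residues, "
         f"mass {params['molecular_mass_da']:.1f} Da, Rg {params['rg_coords_a']:.2f} A, "
         f"starting nchi2 {iq_fit.nchi2:.4g}")


def _on_grid(curve: ScatteringCurve, q: np.ndarray) -> ScatteringCurve:
    """Interpolate a calculator's output onto the experimental grid.

    The internal Debye calculator is asked for the experimental q values
    directly, making this a no-op; external calculators that choose their
    own grid are linearly interpolated (the standard contract).
    """
    if curve.q.shape == q.shape and np.allclose(curve.q, q, rtol=0, atol=1e-12):
        return curve
    return interpolate_to_grid(curve, q)


def _stage_flex(config: ProjectConfig, project: Path) -> None:
    structure = read_structure(config.structure_path)
    if config.auto_flex:
        regions = detect_flexible_regions(
            structure.residue_confidence(),
            threshold=config.flex_threshold,
            min_run=config.flex_min_run,
        )
        mode = f"auto (threshold {config.flex_threshold}, min run {config.flex_min_run})"
    else:
        regions = sorted(parse_region(t) for t in config.manual_regions)
        mode = "manual"
    if not regions:
        raise ValueError("no flexible regions found/entered; cannot proceed to MC")
    align = _resolve_align_range(config, regions, structure.n_residues)
    payload = {
        "mode": mode,
        "regions": [{"start": r.start, "end": r.end} for r in regions],
        "align_range": {"start": align.start, "end": align.end},
    }
    (project / "regions.json").write_text(json.dumps(payload, indent=2))
    _log(project, "flex", f"{mode}: regions " + ", ".join(map(str, regions))
         + f"; alignment {align}")


def _stage_mc(config: ProjectConfig, project: Path) -> None:
    structure = read_structure(config.structure_path)
    regions = _load_regions(project)
    meta = json.loads((project / "regions.json").read_text())
    align = FlexibleRegion(**meta["align_range"])
    mc_config = MCConfig(
        trial_attempts=config.trial_attempts,
        max_angle=config.max_angle,
        temperature=config.temperature,
        return_after_fails=config.return_after_fails,
        overlap_basis=config.overlap_basis,
        align_range=align,
        seed=config.seed,
    )
    pool = run_mc(structure, regions, mc_config)
    if len(pool) == 0:
        raise RuntimeError("Monte Carlo accepted no frames; loosen parameters")
    write_multimodel_pdb(pool, project / "pool.pdb")
    _write_table(
        project / "rg_frames.csv",
        ["model", "trial", "rg"],
        [
            np.array(pool.model_numbers, dtype=float),
            np.array(pool.trial_index, dtype=float),
            pool.rg,
        ],
    )
    with open(project / "acceptance_log.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["trial", "accepted"])
        for i, flag in enumerate(pool.acceptance_log, start=1):
            writer.writerow([i, int(flag)])
    _log(project, "mc",
         f"{len(pool)} accepted of {config.trial_attempts} trials (seed {config.seed})")


def _stage_reduce(config: ProjectConfig, project: Path) -> None:
    pool = read_multimodel_pdb(project / "pool.pdb")
    spec = pool_ops.ReductionSpec(stride=config.stride, offset=config.offset)
    positions = pool_ops.reduce_pool(len(pool), spec)
    reduced = pool.subset_by_position(positions)
    comparison = pool_ops.rg_histogram_compare(pool.rg, reduced.rg)
    write_multimodel_pdb(reduced, project / "reduced.pdb")
    centers = (comparison.bin_edges[:-1] + comparison.bin_edges[1:]) / 2
    _write_table(
        project / "rg_histogram.csv",
        ["rg_bin_center", "freq_full", "freq_reduced"],
        [centers, comparison.hist_full, comparison.hist_reduced],
    )
    (project / "reduction.json").write_text(json.dumps({
        "stride": spec.stride,
        "offset": spec.offset,
        "pool_size": len(pool),
        "reduced_size": len(reduced),
        "positions": positions,
        "rg_tv_distance": comparison.tv_distance,
    }, indent=2))
    _log(project, "reduce",
         f"stride {spec.stride} offset {spec.offset}: {len(reduced)} of {len(pool)} "
         f"frames, Rg TV distance {comparison.tv_distance:.3f}")


def _model_profiles(
    config: ProjectConfig,
    pool: ConformerPool,
    exp_iq: ScatteringCurve,
    exp_pr: PofR,
) -> tuple[np.ndarray, np.ndarray]:
    calc = _CALCULATORS[config.calculator]
    iq_cols, pr_cols = [], []
    for _, s in pool.frames:
        iq_cols.append(_on_grid(calc(s, exp_iq.q), exp_iq.q).intensity)
        pr = compute_pr(s, bin_width=exp_pr.bin_width or 1.0)
        pr_cols.append(pr_on_grid(pr, exp_pr.r).p if pr.r.size <= exp_pr.r.size
                       else pr.p[: exp_pr.r.size])
    return np.stack(iq_cols, axis=1), np.stack(pr_cols, axis=1)


def _stage_profiles(config: ProjectConfig, project: Path) -> None:
    reduced = read_multimodel_pdb(project / "reduced.pdb")
    exp_iq = _load_exp_iq(project)
    exp_pr = _load_exp_pr(project)
    iq_matrix, pr_matrix = _model_profiles(config, reduced, exp_iq, exp_pr)
    labels = [f"m{n}" for n in reduced.model_numbers]
    _write_table(project / "model_iq.csv", ["q", *labels],
                 [exp_iq.q, *iq_matrix.T])
    _write_table(project / "model_pr.csv", ["r", *labels],
                 [exp_pr.r, *pr_matrix.T])
    _log(project, "profiles",
         f"computed {len(labels)} I(q) and P(r) profiles with "
         f"calculator '{config.calculator}'")


def _read_profile_matrix(path: Path) -> tuple[list[int], np.ndarray, np.ndarray]:
    header, data = _read_table(path)
    numbers = [int(h[1:]) for h in header[1:]]
    return numbers, data[:, 0], data[:, 1:]


def _stage_select(config: ProjectConfig, project: Path) -> None:
    numbers, _, iq_matrix = _read_profile_matrix(project / "model_iq.csv")
    _, _, pr_matrix = _read_profile_matrix(project / "model_pr.csv")
    exp_iq = _load_exp_iq(project)
    exp_pr = _load_exp_pr(project)

    iq_fit = ensemble.nnls_select(
        iq_matrix, exp_iq,
        use_sd_weighting=config.use_sd_weighting_iq and exp_iq.sd is not None,
        model_numbers=numbers,
    )
    fits = {"iq": iq_fit, "pr_unweighted": ensemble.nnls_select(
        pr_matrix, PofR(exp_pr.r, exp_pr.p), model_numbers=numbers)}
    if config.pr_sd_weighting and exp_pr.sd is not None:
        fits["pr_sd_weighted"] = ensemble.nnls_select(
            pr_matrix, exp_pr, use_sd_weighting=True, model_numbers=numbers
        )
    payload = {
        name: {
            "model_numbers": fit.model_numbers,
            "percents": [float(p) for p in fit.percents],
            "weights": [float(w) for w in fit.weights],
            "nchi2": fit.nchi2,
        }
        for name, fit in fits.items()
    }
    (project / "preselection.json").write_text(json.dumps(payload, indent=2))
    union = sorted(set().union(*(f.model_numbers for f in fits.values())))
    (project / "preselected_models.json").write_text(json.dumps(union))
    _log(project, "select",
         "preselected models " + ", ".join(map(str, union))
         + f"; I(q) nchi2 {iq_fit.nchi2:.4g}")


def _stage_final(config: ProjectConfig, project: Path) -> None:
    pool = read_multimodel_pdb(project / "pool.pdb")
    preselected = json.loads((project / "preselected_models.json").read_text())
    exp_iq = _load_exp_iq(project)
    exp_pr = _load_exp_pr(project)

    augmented = pool_ops.augment_adjacent(
        preselected, config.adjacent_k, config.stride, len(pool)
    )
    subset = pool.subset_by_position(augmented)
    iq_matrix, pr_matrix = _model_profiles(config, subset, exp_iq, exp_pr)

    fit = ensemble.nnls_select(
        iq_matrix, exp_iq,
        use_sd_weighting=config.use_sd_weighting_iq and exp_iq.sd is not None,
        model_numbers=subset.model_numbers,
    )
    sel_pos = [subset.model_numbers.index(n) for n in fit.model_numbers]
    rg_sel = subset.rg[sel_pos]
    fit.weighted_rg = ensemble.weighted_rg(rg_sel, fit.percents)

    recon_iq, _ = ensemble.reconstruct_curve(iq_matrix[:, sel_pos], fit.weights)
    pr_profiles = [PofR(exp_pr.r, pr_matrix[:, i]) for i in sel_pos]
    composite_pr, pr_rmsd = ensemble.reconstruct_pr(
        pr_profiles, fit.percents, exp_pr
    )

    selected_pool = subset.subset_by_position(
        [subset.model_numbers.index(n) + 1 for n in fit.model_numbers]
    )
    write_multimodel_pdb(selected_pool, project / "selected_models.pdb")
    _write_table(project / "reconstructed_iq.csv", ["q", "I_exp", "I_fit"],
                 [exp_iq.q, exp_iq.intensity, recon_iq])
    _write_table(project / "reconstructed_pr.csv", ["r", "P_exp", "P_fit"],
                 [exp_pr.r, exp_pr.p, composite_pr.p])

    params = json.loads((project / "structure_params.json").read_text())
    payload = {
        "augmented_frames": augmented,
        "adjacent_k": config.adjacent_k,
        "model_numbers": fit.model_numbers,
        "percents": [float(p) for p in fit.percents],
        "rg_per_model_a": [float(r) for r in rg_sel],
        "nchi2": fit.nchi2,
        "weighted_rg_a": fit.weighted_rg,
        "rg_start_a": params["rg_coords_a"],
        "rg_exp_pr_a": params["rg_exp_pr_a"],
        "starting_nchi2": params["iq_nchi2"],
        "pr_rmsd_reconstructed": pr_rmsd,
        "pr_rmsd_start": params["pr_rmsd"],
    }
    (project / "final.json").write_text(json.dumps(payload, indent=2))
    _log(project, "final",
         f"{len(fit.model_numbers)} models selected; nchi2 {fit.nchi2:.4g} "
         f"(start {params['iq_nchi2']:.4g}); weighted Rg {fit.weighted_rg:.2f} A")


def final_report(config: ProjectConfig, workdir: str | Path = ".") -> str:
    """Human-readable end-of-pipeline summary (also written to report.txt).

    Lists each selected model's number, percent contribution and Rg, the
    starting-structure vs ensemble fit quality, and the three reference Rg
    values (starting structure, weighted ensemble, experimental P(r)).
    """
    project = config.project_dir(workdir)
    if not (project / "final.json").exists():
        raise RuntimeError("stage 'final' has not completed; run 'final' first")
    data = json.loads((project / "final.json").read_text())
    lines = [
        f"Project: {config.project_name}",
        "",
        "Selected ensemble (model / percent / Rg A):",
    ]
    for n, p, r in zip(data["model_numbers"], data["percents"], data["rg_per_model_a"]):
        lines.append(f"  {n:>6d}  {p:7.2f} %  {r:8.2f}")
    lines += [
        f"  Total   {sum(data['percents']):7.2f} %",
        "",
        f"Ensemble nchi2:            {data['nchi2']:.4f}",
        f"Starting-structure nchi2:  {data['starting_nchi2']:.4f}",
        f"Reconstructed P(r) RMSD:   {data['pr_rmsd_reconstructed']:.6g}",
        f"Starting P(r) RMSD:        {data['pr_rmsd_start']:.6g}",
        "",
        f"Rg (starting structure):   {data['rg_start_a']:.2f} A",
        f"Rg (weighted ensemble):    {data['weighted_rg_a']:.2f} A",
        f"Rg (experimental P(r)):    {data['rg_exp_pr_a']:.2f} A",
    ]
    text = "\n".join(lines) + "\n"
    (project / "report.txt").write_text(text)
    with open(project / "report.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["model", "percent", "rg_a"])
        for n, p, r in zip(
            data["model_numbers"], data["percents"], data["rg_per_model_a"]
        ):
            writer.writerow([n, f"{p:.6f}", f"{r:.6f}"])
    return text
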