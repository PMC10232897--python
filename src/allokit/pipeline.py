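"""Configuration handling and end-to-end stage orchestration.

A pipeline run takes a trajectory (read from files, or generated by the
synthetic planted-event model), and executes the requested analysis stages
in dependency order:

    contacts -> red                      (contact map, event detection)
    cv -> tica -> msm -> tpt             (kinetic model and pathway fluxes)
    nbit                                 (coordination / allostery measures)

Every output CSV is stamped with the configuration hash, the master seed and
the package version, so a result file can always be traced back to the exact
configuration that produced it.  All randomness derives from the single
``seed`` entry.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import contacts, cvspace, msm, nbit, red, synthetic, tica, tpt, traj_io
from ._version import __version__

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]

log = logging.getLogger("allokit.pipeline")

_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "output_dir": "allokit_out",
    "stages": ["contacts", "red", "cv", "tica", "msm", "tpt", "nbit"],
    "input": {
        "kind": "planted",  # planted | files
        "topology": None,
        "trajectories": None,
        "frame_interval_ns": 1.0,
        "planted": {},
    },
    "contacts": {"cutoff": 3.5, "heavy_only": True, "window_frames": 25},
    "red": {"c": 5, "k_sigma": 4.0, "cv_max": 0.15, "mean_min": 0.5, "max_iter": 2000},
    "cv": {"definitions": None},
    "tica": {"lag_frames": 25, "k": 3},
    "msm": {"n_microstates": 200, "lag_frames": 25, "n_macrostates": 9},
    "tpt": {"source": None, "target": None, "coverage": 0.95},
    "nbit": {
        "motifs": None,
        "atom_policy": "heavy",
        "mode": "scalar",
        "align_residues": None,
    },
}

_STAGE_ORDER = ["contacts", "red", "cv", "tica", "msm", "tpt", "nbit"]
_STAGE_DEPS = {
    "red": ["contacts"],
    "tica": ["cv"],
    "msm": ["tica"],
    "tpt": ["msm"],
}


@dataclass
class PipelineConfig:
    data: dict[str, Any]

    def __getitem__(self, key: str) -> Any:
        return self.data[key]

    @property
    def config_hash(self) -> str:
        """Hash of the analysis parameters (the output location is excluded)."""
        payload = {k: v for k, v in self.data.items() if k != "output_dir"}
        canon = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _merge(defaults: Mapping, given: Mapping, path: str = "") -> dict:
    out = dict(defaults)
    for key, value in given.items():
        if key not in defaults:
            raise ValueError(f"unknown configuration key {path + key!r}")
        if defaults[key] == {}:  # open subtree, validated downstream
            out[key] = dict(value)
        elif isinstance(defaults[key], dict) and isinstance(value, Mapping):
            out[key] = _merge(defaults[key], value, path + key + ".")
        else:
            out[key] = value
    return out


def validate_config(source: str | Path | Mapping) -> PipelineConfig:
    """Parse and validate a YAML/JSON file or a mapping into a full config.

    Missing keys receive defaults (contact cutoff 3.5 A, smoothing window 25
    frames, 5 RED components, 200 microstates, 4-sigma SDCP threshold, ...);
    unknown keys are a hard error.
    """
    if isinstance(source, (str, Path)):
        with open(source) as f:
            raw = yaml.safe_load(f)
        if raw is None:
            raw = {}
    else:
        raw = dict(source)
    if not isinstance(raw, Mapping):
        raise ValueError("configuration root must be a mapping")
    data = _merge(_DEFAULTS, raw)
    for stage in data["stages"]:
        if stage not in _STAGE_ORDER:
            raise ValueError(f"unknown stage {stage!r}")
        for dep in _STAGE_DEPS.get(stage, []):
            if dep not in data["stages"]:
                raise ValueError(f"stage {stage!r} requires stage {dep!r}")
    if data["input"]["kind"] not in ("planted", "files"):
        raise ValueError(f"unknown input kind {data['input']['kind']!r}")
    if data["input"]["kind"] == "files":
        if not data["input"]["topology"] or not data["input"]["trajectories"]:
            raise ValueError("input.kind 'files' requires 'topology' and 'trajectories'")
    return PipelineConfig(data=data)


def _provenance_header(config: PipelineConfig) -> str:
    return (
        f"# allokit {__version__} | config_hash={config.config_hash} "
        f"| seed={config['seed']}\n"
    )


def _write_csv(df: pd.DataFrame, path: Path, config: PipelineConfig, index: bool = False) -> None:
    with open(path, "w") as f:
        f.write(_provenance_header(config))
        df.to_csv(f, index=index)
    log.info("wrote %s", path)


def _load_input(config: PipelineConfig):
    inp = config["input"]
    if inp["kind"] == "files":
        topology, ref = traj_io.read_structure(inp["topology"])
        traj = traj_io.read_trajectory(
            inp["trajectories"], topology, frame_interval_ns=inp["frame_interval_ns"]
        )
        return traj, ref, None
    spec_kwargs = dict(inp["planted"])
    spec_kwargs.setdefault("seed", config["seed"])
    if "states" in spec_kwargs:
        spec_kwargs["states"] = [frozenset(map(tuple, s)) for s in spec_kwargs["states"]]
    spec_kwargs.setdefault("ligand_sites", None)
    if spec_kwargs["ligand_sites"] is None:
        # default planted model: ligand hops between two site residues at the event
        spec_kwargs["ligand_sites"] = None
        spec = synthetic.PlantedEventSpec(**spec_kwargs)
        n_states = len(spec.states)
        spec_kwargs["ligand_sites"] = [1 + (k * (spec.n_residues // 2)) % spec.n_residues for k in range(n_states)]
    spec = synthetic.PlantedEventSpec(**spec_kwargs)
    traj, truth = synthetic.gen_planted_trajectory(spec)
    ref_top = traj.topology
    ref = traj_io.Trajectory(ref_top, traj.coords[:1].copy())
    return traj, ref, truth


def _default_cv_config(traj, truth) -> list[dict]:
    lig = truth.ligand_residue_id
    sites = truth.ligand_sites
    defs = []
    if lig is not None and sites:
        for tag, site in (("site_a", sites[0]), ("site_b", sites[-1])):
            defs.append(
                {
                    "name": f"lig_{tag}_dist",
                    "type": "com_distance",
                    "group_a": {"residue_ids": [lig]},
                    "group_b": {"residue_ids": [site]},
                }
            )
    for i, j in truth.switching_pairs[:5]:
        defs.append(
            {
                "name": f"pair_{i}_{j}_dist",
                "type": "com_distance",
                "group_a": {"residue_ids": [i]},
                "group_b": {"residue_ids": [j]},
            }
        )
    return defs


def run_pipeline(config: PipelineConfig | Mapping | str | Path) -> Path:
    """Execute the configured stages; returns the output directory.

    Stage outputs: contact pair index and matrix, SDCP and temporal-weight
    tables from event detection, the CV matrix, tICA projections, MSM
    populations and implied timescales, TPT pathway fluxes, and the
    coordination (TC/NCI) matrix.  Deterministic for a fixed configuration.
    """
    if not isinstance(config, PipelineConfig):
        config = validate_config(config)
    out = Path(config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    stages = [s for s in _STAGE_ORDER if s in config["stages"]]
    seed = int(config["seed"])

    current = "input"
    try:
        traj, ref, truth = _load_input(config)

        cts_smoothed = None
        if "contacts" in stages:
            current = "contacts"
            ccfg = config["contacts"]
            cts = contacts.compute_contact_series(
                traj, cutoff=ccfg["cutoff"], heavy_only=ccfg["heavy_only"]
            )
            cts = contacts.trim_invariant_pairs(cts)
            cts_smoothed = contacts.smooth(cts, window_frames=ccfg["window_frames"])
            _write_csv(
                pd.DataFrame(cts.pair_index, columns=["res_i", "res_j"]),
                out / "contact_pairs.csv",
                config,
            )
            np.savez_compressed(
                out / "contact_matrix.npz",
                values=cts_smoothed.values,
                segment_boundaries=np.asarray(cts.segment_boundaries),
            )

        if "red" in stages:
            current = "red"
            rcfg = config["red"]
            model = red.fit_red(
                cts_smoothed, c=rcfg["c"], seed=seed, max_iter=rcfg["max_iter"]
            )
            try:
                constitutive = red.identify_constitutive_pairs(
                    model, cv_max=rcfg["cv_max"], mean_min=rcfg["mean_min"]
                )
            except ValueError:
                constitutive = list(model.pair_index)  # fall back: normalize on all pairs
            model = red.normalize_components(model, constitutive)
            weights, labels, transitions = red.dominance_timeline(model)
            _write_csv(
                pd.DataFrame(
                    weights, columns=[f"component_{k}" for k in range(model.n_components)]
                ).assign(dominant=labels),
                out / "red_temporal_weights.csv",
                config,
            )
            comps = sorted(set(labels[[0, -1]])) if len(set(labels)) > 1 else [0, model.n_components - 1]
            sdcps = red.extract_sdcps(model, comps[0], comps[-1], k_sigma=rcfg["k_sigma"])
            _write_csv(sdcps, out / "red_sdcps.csv", config)

        cv_matrix = None
        if "cv" in stages:
            current = "cv"
            defs = config["cv"]["definitions"]
            if defs is None:
                if truth is None:
                    raise ValueError("cv.definitions required for file inputs")
                defs = _default_cv_config(traj, truth)
            cv_matrix = cvspace.build_cv_matrix(traj, defs)
            _write_csv(cv_matrix.to_frame(), out / "cv_matrix.csv", config)
            # contact-probability report over the dynamic pairs
            if truth is not None:
                rows = [
                    {
                        "res_i": i,
                        "res_j": j,
                        "probability_percent": cvspace.contact_probability(traj, i, j),
                    }
                    for i, j in truth.switching_pairs
                ]
                _write_csv(
                    pd.DataFrame(rows), out / "contact_probabilities.csv", config
                )

        projections = None
        if "tica" in stages:
            current = "tica"
            tcfg = config["tica"]
            segs = [cv_matrix.values[s] for s in _segment_slices(cv_matrix)]
            tica_model = tica.fit_tica(segs, lag_frames=tcfg["lag_frames"])
            k = min(tcfg["k"], tica_model.n_cv)
            projections = [tica.project(tica_model, s, k=k) for s in segs]
            _write_csv(
                pd.DataFrame(
                    np.concatenate(projections), columns=[f"tic{i + 1}" for i in range(k)]
                ),
                out / "tica_projections.csv",
                config,
            )

        markov = None
        macro = None
        if "msm" in stages:
            current = "msm"
            mcfg = config["msm"]
            clustering = msm.cluster_microstates(
                projections, k=mcfg["n_microstates"], seed=seed
            )
            markov = msm.build_tpm(clustering.assignments, lag_frames=mcfg["lag_frames"])
            m = min(mcfg["n_macrostates"], markov.n_states)
            macro = msm.pcca_macrostates(markov, m=m)
            _write_csv(
                pd.DataFrame(
                    {
                        "macrostate": np.arange(m),
                        "population": macro.populations,
                    }
                ),
                out / "msm_macrostate_populations.csv",
                config,
            )

        if "tpt" in stages:
            current = "tpt"
            pcfg = config["tpt"]
            pops = macro.populations
            source = pcfg["source"] if pcfg["source"] is not None else [int(np.argmax(pops))]
            if pcfg["target"] is not None:
                target = pcfg["target"]
            else:
                order = np.argsort(pops)[::-1]
                target = [int(next(s for s in order if s not in source))]
            result = tpt.tpt_analysis(
                macro.macro_tpm, pops / pops.sum(), source, target, coverage=pcfg["coverage"]
            )
            _write_csv(result.pathway_table(), out / "tpt_pathways.csv", config)

        if "nbit" in stages:
            current = "nbit"
            ncfg = config["nbit"]
            align_res = ncfg["align_residues"]
            sel = traj_io.AtomSelection.make(residue_ids=align_res)
            aligned = traj_io.superpose(traj, ref, sel)
            motif_map = ncfg["motifs"]
            if motif_map is None:
                if truth is None:
                    raise ValueError("nbit.motifs required for file inputs")
                motif_map = _default_motifs(truth)
            ensembles = {
                name: nbit.displacement_ensemble(
                    aligned,
                    residues,
                    ref,
                    name=name,
                    atom_policy=ncfg["atom_policy"],
                    mode=ncfg["mode"],
                )
                for name, residues in motif_map.items()
            }
            matrix = nbit.coordination_matrix(ensembles)
            _write_csv(matrix, out / "nbit_coordination_matrix.csv", config, index=True)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "config_hash": config.config_hash,
        "seed": seed,
        "stages": stages,
        "config": config.data,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def _default_motifs(truth) -> dict[str, list[int]]:
    motifs: dict[str, list[int]] = {}
    for k, (i, j) in enumerate(truth.switching_pairs[:3]):
        motifs[f"pair{k}"] = [i, j]
    if len(motifs) < 2:
        raise ValueError("not enough switching pairs to define motifs")
    return motifs


def _segment_slices(cv_matrix) -> list[slice]:
    bounds = list(cv_matrix.segment_boundaries) + [cv_matrix.n_frames]
    return [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]
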