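"""Shared plumbing for the numbered analysis drivers."""

from __future__ import annotations

import argparse
from pathlib import Path

from dieltx import RunConfig
from dieltx import io as dio

HERE = Path(__file__).resolve().parent
ROOT = HERE.parent


def load_config() -> RunConfig:
    parser = argparse.ArgumentParser()
    parser.add_argument("--config", type=Path, default=HERE / "config.yaml")
    args = parser.parse_args()
    cfg = RunConfig.from_yaml(args.config)
    # resolve the results directory relative to the repository root
    cfg.out_dir = str((ROOT / cfg.out_dir).resolve())
    return cfg


def input_paths(cfg: RunConfig) -> dict[str, Path]:
    d = Path(cfg.out_dir) / "inputs"
    return {
        k: d / f"{k}.tsv"
        for k in ("counts", "annotations", "taxonomy", "samples", "pathways",
                  "reference_presence")
    }


def load_inputs(cfg: RunConfig):
    paths = input_paths(cfg)
    contigs = dio.read_contig_table(paths["counts"], paths["annotations"])
    taxonomy = dio.read_taxonomy(paths["taxonomy"])
    samples = dio.read_samples(paths["samples"])
    design = dio.design_from_samples(samples, cfg.period_hours)
    return contigs, taxonomy, samples, design
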