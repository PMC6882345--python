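"""Shared fixtures: tiny hand-written input files and a small simulated
dataset threaded through the whole pipeline."""

from __future__ import annotations

import pytest

from gwasgrid import binning, classify, io_formats, render, synthetic_data


@pytest.fixture(scope="session")
def default_rules():
    rules, _ = io_formats.default_config()
    return rules


@pytest.fixture(scope="session")
def default_options():
    _, options = io_formats.default_config()
    return options


SUMMARY_TSV = """\
name\tchrom\tpos\tpvalue\tmaf\tconsequence
rs1\t1\t1000\t0.5\t0.3\tintron_variant
rs2\t1\t2000\t0.01\t0.04\tstop_gained
rs3\t2\t500\t1e-9\t0.2\tmissense_variant
"""


@pytest.fixture
def summary_file(tmp_path):
    path = tmp_path / "summary.tsv"
    path.write_text(SUMMARY_TSV)
    return path


@pytest.fixture(scope="session")
def small_pipeline(tmp_path_factory, default_rules, default_options):
    """A 20k-variant simulated dataset run through the full pipeline once."""
    out = tmp_path_factory.mktemp("sim")
    summary, loci_path, truth = synthetic_data.simulate_gwas(
        20_000, 8, seed=11, out_dir=out
    )
    layout = binning.build_layout(io_formats.read_summary_stats(summary), default_options.chunk_bp)
    matrix = binning.accumulate(
        io_formats.read_summary_stats(summary), layout, default_options
    )
    boundary = classify.significance_boundary(matrix.pvalues, default_options)
    cells = classify.classify_matrix(matrix, default_rules, boundary)
    key = classify.key_counts(cells, matrix, default_rules)
    loci = io_formats.read_loci_table(loci_path)
    spec = render.PlotSpec(
        layout=layout, matrix=matrix, cells=cells, boundary=boundary, key=key,
        rules=default_rules, loci=loci, mode="table", options=default_options,
    )
    return {
        "summary": summary, "loci_path": loci_path, "truth": truth, "layout": layout,
        "matrix": matrix, "boundary": boundary, "cells": cells, "key": key,
        "loci": loci, "spec": spec,
    }
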