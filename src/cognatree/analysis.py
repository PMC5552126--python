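"""Model/Results front end tying the pipeline together.

:class:`PhylogeneticAnalysis` is built from data (directly, or from a
parsed configuration via :meth:`from_config`, which runs the whole
preprocessing pipeline: layout detection, language selection, borrowing
recoding, coverage and degeneracy filtering, binarization, constraint and
calibration resolution).  Its :meth:`fit` runs the MCMC and returns an
:class:`AnalysisResults` carrying the posterior sample, parameter
summaries and the output writers.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classification import (Classification, load_classification,
                             load_phylotree, locations as clade_locations,
                             monophyly_constraints, prune_fixed_tree,
                             resolve_clade, select_languages)
from .config import AnalysisConfig, provenance_header, render_config
from .data_io import (DataTable, RemovalLog, combine, coverage_filter,
                      drop_degenerate, filter_languages, read_long,
                      read_matrix, LANGUAGE_COLUMNS, FEATURE_COLUMNS,
                      VALUE_COLUMNS)
from .errors import ConfigurationError, DataError
from .inference import (PatternBlock, SampleLog, prepare_block, run_mcmc,
                        run_fixed_tree)
from .phylo import PhyloTree
from .recode import binarize, is_binary, recode_borrowings
from .summarize import (PosteriorSample, clade_support, mcc_tree,
                        rate_summary, write_map, write_report,
                        write_trace_tsv, write_trees_nexus)
from .treeprior import CalibrationSpec


def _detect_layout(text: str) -> str:
    header = text.splitlines()[0].lower() if text.strip() else ""
    cols = {c.strip() for c in header.replace("\t", ",").split(",")}
    if (cols & set(LANGUAGE_COLUMNS)) and (cols & set(FEATURE_COLUMNS)) \
            and (cols & set(VALUE_COLUMNS)):
        return "long"
    return "matrix"


@dataclass
class PhylogeneticAnalysis:
    """A fully prepared analysis, ready to sample.

    Construct directly from compiled blocks, or use :meth:`from_config`.
    """

    blocks: list[PatternBlock]
    clock_specs: dict[str, dict]
    chain_length: int
    sample_interval: int
    constraints: list[frozenset] = field(default_factory=list)
    calibrations: list[CalibrationSpec] = field(default_factory=list)
    fixed_tree: PhyloTree | None = None
    prior_only: bool = False
    basename: str = "cognatree"
    config_text: str = ""
    tables: list[DataTable] = field(default_factory=list)
    embed_data: bool = False
    locations: dict[str, tuple[float, float]] = field(default_factory=dict)
    families: dict[str, list[str]] | None = None
    classification: Classification | None = None

    # -- construction ------------------------------------------------------
    @classmethod
    def from_config(cls, cfg: AnalysisConfig,
                    base_dir: str | Path = ".") -> "PhylogeneticAnalysis":
        base = Path(base_dir)

        classification = None
        if cfg.classification_path:
            newick = (base / cfg.classification_path).read_text()
            sidecar_path = (base / cfg.classification_path).with_suffix(".csv")
            sidecar = sidecar_path.read_text() if sidecar_path.exists() else None
            classification = load_classification(newick, sidecar)

        # 1. read every model block's table
        raw_tables: list[DataTable] = []
        for mb in cfg.model_blocks:
            text = (base / mb.data_path).read_text()
            layout = mb.layout if mb.layout != "auto" else _detect_layout(text)
            table = (read_long(text) if layout == "long"
                     else read_matrix(text))
            table.source = mb.data_path
            raw_tables.append(table)

        # 2. language selection across all blocks
        all_langs: list[str] = []
        for t in raw_tables:
            for l in t.languages:
                if l not in all_langs:
                    all_langs.append(l)
        lf = cfg.language_filters
        if classification is not None and (lf.families or lf.macroareas
                                           or lf.exclusions):
            selected = select_languages(classification, lf.families,
                                        lf.macroareas, lf.exclusions,
                                        all_langs)
        else:
            selected = set(all_langs) - set(lf.exclusions)
        raw_tables = [filter_languages(t, selected) for t in raw_tables]
        raw_tables = combine(raw_tables, lf.overlap_mode)
        languages = list(raw_tables[0].languages)

        # 3. per-block feature pipeline
        blocks: list[PatternBlock] = []
        clean_tables: list[DataTable] = []
        for mb, table in zip(cfg.model_blocks, raw_tables):
            if mb.features:
                keep = [f for f in table.features if f in set(mb.features)]
                table = DataTable(list(table.languages), keep,
                                  {k: v for k, v in table.cells.items()
                                   if k[1] in set(keep)}, table.source)
            if mb.exclude_features:
                drop = set(mb.exclude_features)
                keep = [f for f in table.features if f not in drop]
                table = DataTable(list(table.languages), keep,
                                  {k: v for k, v in table.cells.items()
                                   if k[1] not in drop}, table.source)
            if mb.recode_borrowings:
                table = recode_borrowings(table)
            log = RemovalLog()
            if mb.minimum_coverage > 0:
                table, cov_log = coverage_filter(table, mb.minimum_coverage)
                log = log.merge(cov_log)
            table, degen_log = drop_degenerate(table)
            log = log.merge(degen_log)
            binarized = False
            if mb.binarize == "always" or (
                    mb.binarize == "auto" and mb.model_kind == "covarion"
                    and not is_binary(table)):
                table, recodings = binarize(table)
                binarized = bool(recodings)
                table, _ = drop_degenerate(table)
            clean_tables.append(table)
            blocks.append(prepare_block(
                mb.name, table, model_kind=mb.model_kind,
                frequencies=mb.frequencies,
                rate_variation=mb.rate_variation, clock_name=mb.clock,
                removal_log=log, binarized=binarized))

        # 4. constraints, calibrations, fixed tree, locations
        constraints: list[frozenset] = []
        if cfg.monophyly and classification is not None:
            constraints = [c.leaves for c in
                           monophyly_constraints(classification, languages)]
        calibrations: list[CalibrationSpec] = []
        for clade, lo, hi in cfg.calibrations:
            if clade.lower() == "root":
                calibrations.append(CalibrationSpec("root", lo, hi))
                continue
            if classification is None:
                raise ConfigurationError(
                    f"calibration on clade {clade!r} needs a classification")
            ids = resolve_clade(classification, clade) & set(languages)
            if len(ids) < 2:
                raise ConfigurationError(
                    f"calibration clade {clade!r} covers fewer than 2 "
                    "data languages")
            calibrations.append(CalibrationSpec(frozenset(ids), lo, hi))

        fixed_tree = None
        if cfg.fixed_tree_path:
            full = load_phylotree((base / cfg.fixed_tree_path).read_text())
            fixed_tree = prune_fixed_tree(full, languages)
            missing = set(languages) - set(fixed_tree.leaf_labels)
            if missing:
                # languages absent from the fixed tree cannot be analysed
                blocks = [prepare_block(
                    b.name, filter_languages(t, set(fixed_tree.leaf_labels)),
                    model_kind=b.model_kind, frequencies=b.frequencies,
                    rate_variation=b.rate_variation, clock_name=b.clock_name,
                    binarized=b.ascertainment)
                    for b, t in zip(blocks, clean_tables)]
                languages = list(fixed_tree.leaf_labels)

        locs: dict[str, tuple[float, float]] = {}
        families: dict[str, list[str]] | None = None
        if classification is not None:
            override = None
            if cfg.location_override_path:
                override = (base / cfg.location_override_path).read_text()
            locs = clade_locations(classification, languages, override)
            if lf.families:
                families = {}
                for fam in lf.families:
                    ids = resolve_clade(classification, fam) & set(languages)
                    if ids:
                        families[fam] = sorted(ids)

        clock_specs = {c.name: {"kind": c.kind,
                                "distribution": c.relaxed_distribution}
                       for c in cfg.clock_blocks}

        return cls(blocks=blocks, clock_specs=clock_specs,
                   chain_length=cfg.chain_length,
                   sample_interval=cfg.sample_interval,
                   constraints=constraints, calibrations=calibrations,
                   fixed_tree=fixed_tree, prior_only=cfg.prior_only,
                   basename=cfg.basename, config_text=render_config(cfg),
                   tables=clean_tables, embed_data=cfg.embed_data,
                   locations=locs, families=families,
                   classification=classification)

    # -- fitting -----------------------------------------------------------
    def fit(self, seed: int = 0) -> "AnalysisResults":
        """Run the MCMC and wrap the sample streams in a results object."""
        timestamp = datetime.datetime.now().isoformat(timespec="seconds")
        header = provenance_header(self.config_text, self.tables,
                                   version=__version__, timestamp=timestamp,
                                   embed_data=self.embed_data)
        header += f"# seed = {seed}\n"
        if self.fixed_tree is not None:
            log = run_fixed_tree(self.blocks, self.clock_specs,
                                 self.fixed_tree, self.chain_length,
                                 self.sample_interval,
                                 calibrations=self.calibrations,
                                 seed=seed, header=header)
        else:
            log = run_mcmc(self.blocks, self.clock_specs, self.chain_length,
                           self.sample_interval,
                           constraints=self.constraints,
                           calibrations=self.calibrations, seed=seed,
                           prior_only=self.prior_only, header=header)
        return AnalysisResults(self, log)


class AnalysisResults:
    """Posterior sample with summaries and writers."""

    def __init__(self, model: PhylogeneticAnalysis, log: SampleLog,
                 burnin: float = 0.1):
        self.model = model
        self.log = log
        self.burnin = burnin
        self.posterior = PosteriorSample.from_log(log, burnin)

    # -- summaries ---------------------------------------------------------
    def params(self) -> pd.DataFrame:
        """Posterior mean/sd and central 95% interval per scalar column."""
        rows = []
        for col in self.posterior.trace.columns:
            if col == "sample":
                continue
            x = self.posterior.trace[col].to_numpy(dtype=float)
            rows.append({
                "parameter": col,
                "mean": float(np.mean(x)),
                "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
                "hpd2.5": float(np.quantile(x, 0.025)),
                "hpd97.5": float(np.quantile(x, 0.975)),
            })
        return pd.DataFrame(rows).set_index("parameter")

    def summary(self, max_rows: int = 40) -> str:
        df = self.params()
        lines = [f"Posterior summary ({self.model.basename}); "
                 f"{len(self.posterior.trace)} samples after "
                 f"{self.burnin:.0%} burn-in",
                 df.head(max_rows).to_string(float_format=lambda v: f"{v:.4f}")]
        if len(df) > max_rows:
            lines.append(f"... ({len(df) - max_rows} more parameters)")
        return "\n".join(lines)

    def rate_summary(self, block: str | None = None) -> pd.DataFrame:
        if block is None:
            block = self.model.blocks[0].name
        return rate_summary(self.posterior.trace, block)

    def clade_support(self, leaves) -> float:
        return clade_support(self.posterior, leaves)

    def mcc_tree(self) -> PhyloTree:
        return mcc_tree(self.posterior)

    # -- output files ------------------------------------------------------
    def save(self, outdir: str | Path, overwrite: bool = False,
             report: bool = False) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        base = self.model.basename
        written: list[Path] = []

        def emit(name: str, text: str) -> None:
            path = outdir / name
            if path.exists() and not overwrite:
                raise DataError(f"{path} exists (use overwrite)")
            path.write_text(text)
            written.append(path)

        emit(f"{base}.log", write_trace_tsv(self.log))
        if self.log.trees is not None:
            emit(f"{base}.trees", write_trees_nexus(self.log))
            emit(f"{base}.mcc.nex", "#NEXUS\n[\n" + self.log.header
                 + "]\nbegin trees;\ntree MCC = "
                 + self.mcc_tree().to_newick(fmt="%.8g") + "\nend;\n")
        if report:
            model_lines = [
                f"{b.name}: {b.model_kind}, {b.n_features} features, "
                f"{'rate variation, ' if b.rate_variation else ''}"
                f"{b.frequencies} frequencies, "
                f"ascertainment {'on' if b.ascertainment else 'off'}"
                for b in self.model.blocks]
            clock_lines = [
                f"{name}: {spec['kind']}"
                + (f" ({spec['distribution']})" if spec.get("distribution")
                   else "")
                for name, spec in self.model.clock_specs.items()]
            cals = [(c.clade if isinstance(c.clade, str)
                     else "+".join(sorted(c.clade)), c.lower, c.upper)
                    for c in self.model.calibrations]
            emit(f"{base}.md", write_report(
                base, self.model.blocks[0].languages, self.model.families,
                model_lines, clock_lines, cals,
                self.model.locations or None, provenance=self.log.header))
            if self.model.locations:
                emit(f"{base}.geojson", write_map(self.model.locations,
                                                  provenance=self.log.header))
        return written
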