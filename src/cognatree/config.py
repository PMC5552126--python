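"""The INI-style analysis configuration dialect.

An analysis is described by short, hand-editable section/key files::

    [admin]
    basename = austronesian_wals
    [MCMC]
    chainlength = 50000000
    [languages]
    families = Austronesian
    monophyly = True
    [model wals]
    data = wals_data.csv
    model = mk
    rate_variation = True
    [clock default]
    type = relaxed
    [calibration]
    root = 4700 - 5700

Several files can be layered; keys set in later files override the same key
in earlier files, while sections and keys only present in earlier files
persist.  Section and key names are case-insensitive; values keep their
case.  Unknown sections or keys produce warnings, never errors, so configs
written for richer dialects degrade gracefully.
"""

from __future__ import annotations

import configparser
import io
import re
import warnings
from dataclasses import dataclass, field

from .errors import ConfigurationError

#: Default number of MCMC steps when [MCMC] gives no chainlength, and the
#: ratio used to derive the sampling interval (10,000 samples per chain).
DEFAULT_CHAIN_LENGTH = 10_000_000
SAMPLES_PER_CHAIN = 10_000

KNOWN_SECTIONS = {"admin", "mcmc", "languages", "calibration"}
KNOWN_ADMIN_KEYS = {"basename", "embed_data"}
KNOWN_MCMC_KEYS = {"chainlength", "sample_interval", "sample_from_prior"}
KNOWN_LANGUAGE_KEYS = {"families", "macroareas", "exclusions", "overlap",
                       "monophyly", "tree", "classification", "locations"}
KNOWN_MODEL_KEYS = {"data", "layout", "model", "rate_variation", "frequencies",
                    "features", "exclude_features", "minimum_coverage",
                    "recode_borrowings", "binarize", "clock"}
KNOWN_CLOCK_KEYS = {"type", "distribution", "calibration_shape"}

_CAL_RE = re.compile(
    r"^\s*([0-9][0-9,]*(?:\.[0-9]+)?)\s*-\s*([0-9][0-9,]*(?:\.[0-9]+)?)\s*$")

MODEL_KINDS = ("mk", "bsvs", "covarion")
CLOCK_KINDS = ("strict", "relaxed", "random_local")
RELAXED_DISTRIBUTIONS = ("lognormal", "exponential", "gamma")


def _parse_bool(value: str, context: str) -> bool:
    v = value.strip().lower()
    if v in ("true", "yes", "on", "1"):
        return True
    if v in ("false", "no", "off", "0"):
        return False
    raise ConfigurationError(f"{context}: not a boolean: {value!r}")


def _parse_int(value: str, context: str) -> int:
    try:
        return int(value.replace(",", ""))
    except ValueError:
        raise ConfigurationError(f"{context}: not an integer: {value!r}")


def _parse_list(value: str) -> list[str]:
    return [v.strip() for v in value.split(",") if v.strip()]


def parse_calibration_range(value: str) -> tuple[float, float]:
    """Parse ``"A - B"`` (thousands separators allowed) into (lower, upper)."""
    m = _CAL_RE.match(value)
    if m is None:
        try:
            x = float(value.replace(",", ""))
            return x, x
        except ValueError:
            raise ConfigurationError(f"cannot parse calibration {value!r}")
    lower = float(m.group(1).replace(",", ""))
    upper = float(m.group(2).replace(",", ""))
    if lower > upper:
        raise ConfigurationError(
            f"calibration lower bound {lower} exceeds upper bound {upper}")
    return lower, upper


@dataclass
class ModelBlock:
    """One dataset together with its substitution model settings."""

    name: str
    data_path: str
    layout: str = "auto"              # matrix | long | auto
    model_kind: str = "mk"            # mk | bsvs | covarion
    rate_variation: bool = False
    frequencies: str = "empirical"    # empirical | uniform
    features: list[str] = field(default_factory=list)
    exclude_features: list[str] = field(default_factory=list)
    minimum_coverage: float = 0.0
    recode_borrowings: bool = False
    binarize: str = "auto"            # auto | always | never
    clock: str = "default"


@dataclass
class ClockBlock:
    name: str
    kind: str = "strict"              # strict | relaxed | random_local
    relaxed_distribution: str | None = None


@dataclass
class LanguageFilters:
    families: list[str] = field(default_factory=list)
    macroareas: list[str] = field(default_factory=list)
    exclusions: list[str] = field(default_factory=list)
    overlap_mode: str = "union"


@dataclass
class AnalysisConfig:
    """Validated, fully-defaulted description of one analysis."""

    basename: str = "cognatree"
    chain_length: int = DEFAULT_CHAIN_LENGTH
    sample_interval: int = DEFAULT_CHAIN_LENGTH // SAMPLES_PER_CHAIN
    language_filters: LanguageFilters = field(default_factory=LanguageFilters)
    monophyly: bool = False
    model_blocks: list[ModelBlock] = field(default_factory=list)
    clock_blocks: list[ClockBlock] = field(default_factory=list)
    calibrations: list[tuple[str, float, float]] = field(default_factory=list)
    fixed_tree_path: str | None = None
    classification_path: str | None = None
    location_override_path: str | None = None
    embed_data: bool = False
    prior_only: bool = False
    raw_sections: dict = field(default_factory=dict, compare=False, repr=False)

    def clock_for(self, block: ModelBlock) -> ClockBlock:
        for c in self.clock_blocks:
            if c.name == block.clock:
                return c
        raise ConfigurationError(f"no clock named {block.clock!r}")


def _read_sections(text: str) -> dict[str, dict[str, str]]:
    """Parse INI text into {section(lower): {key(lower): value}}."""
    cp = configparser.ConfigParser(
        interpolation=None, strict=False, delimiters=("=",),
        comment_prefixes=("#", ";"), inline_comment_prefixes=("#", ";"))
    cp.optionxform = str.lower
    try:
        cp.read_string(text)
    except configparser.Error as e:
        raise ConfigurationError(f"malformed configuration: {e}") from e
    out: dict[str, dict[str, str]] = {}
    for section in cp.sections():
        sec = re.sub(r"\s+", " ", section.strip().lower())
        out.setdefault(sec, {}).update(
            {k.strip().lower(): v.strip() for k, v in cp.items(section)})
    return out


def _merge_sections(layers: list[dict[str, dict[str, str]]]) -> dict[str, dict[str, str]]:
    merged: dict[str, dict[str, str]] = {}
    for layer in layers:
        for sec, kv in layer.items():
            merged.setdefault(sec, {}).update(kv)
    return merged


def _build(sections: dict[str, dict[str, str]]) -> AnalysisConfig:
    cfg = AnalysisConfig(raw_sections=sections)

    admin = sections.get("admin", {})
    for key in admin:
        if key not in KNOWN_ADMIN_KEYS:
            warnings.warn(f"[admin] ignoring unknown key {key!r}")
    cfg.basename = admin.get("basename", cfg.basename)
    if "embed_data" in admin:
        cfg.embed_data = _parse_bool(admin["embed_data"], "[admin] embed_data")

    mcmc = sections.get("mcmc", {})
    for key in mcmc:
        if key not in KNOWN_MCMC_KEYS:
            warnings.warn(f"[MCMC] ignoring unknown key {key!r}")
    if "chainlength" in mcmc:
        cfg.chain_length = _parse_int(mcmc["chainlength"], "[MCMC] chainlength")
    cfg.sample_interval = max(1, cfg.chain_length // SAMPLES_PER_CHAIN)
    if "sample_interval" in mcmc:
        cfg.sample_interval = _parse_int(mcmc["sample_interval"],
                                         "[MCMC] sample_interval")
    if "sample_from_prior" in mcmc:
        cfg.prior_only = _parse_bool(mcmc["sample_from_prior"],
                                     "[MCMC] sample_from_prior")
    if cfg.chain_length < 1:
        raise ConfigurationError("chainlength must be >= 1")
    if not 1 <= cfg.sample_interval <= cfg.chain_length:
        raise ConfigurationError(
            "sample_interval must be in [1, chainlength]")

    langs = sections.get("languages", {})
    for key in langs:
        if key not in KNOWN_LANGUAGE_KEYS:
            warnings.warn(f"[languages] ignoring unknown key {key!r}")
    lf = cfg.language_filters
    lf.families = _parse_list(langs.get("families", ""))
    lf.macroareas = _parse_list(langs.get("macroareas", ""))
    lf.exclusions = _parse_list(langs.get("exclusions", ""))
    lf.overlap_mode = langs.get("overlap", "union").strip().lower()
    if lf.overlap_mode not in ("union", "intersection"):
        raise ConfigurationError(
            f"[languages] overlap must be union or intersection, "
            f"got {lf.overlap_mode!r}")
    if "monophyly" in langs:
        cfg.monophyly = _parse_bool(langs["monophyly"], "[languages] monophyly")
    cfg.fixed_tree_path = langs.get("tree") or None
    cfg.classification_path = langs.get("classification") or None
    cfg.location_override_path = langs.get("locations") or None

    for sec, kv in sections.items():
        if sec.startswith("model ") or sec == "model":
            name = sec[len("model"):].strip() or "model"
            for key in kv:
                if key not in KNOWN_MODEL_KEYS:
                    warnings.warn(f"[{sec}] ignoring unknown key {key!r}")
            if "data" not in kv:
                raise ConfigurationError(f"[{sec}] needs a data = <path> key")
            block = ModelBlock(name=name, data_path=kv["data"])
            block.layout = kv.get("layout", "auto").strip().lower()
            if block.layout not in ("matrix", "long", "auto"):
                raise ConfigurationError(f"[{sec}] unknown layout {block.layout!r}")
            block.model_kind = kv.get("model", "mk").strip().lower()
            if block.model_kind not in MODEL_KINDS:
                raise ConfigurationError(
                    f"[{sec}] unknown model {block.model_kind!r} "
                    f"(expected one of {MODEL_KINDS})")
            if "rate_variation" in kv:
                block.rate_variation = _parse_bool(kv["rate_variation"],
                                                   f"[{sec}] rate_variation")
            block.frequencies = kv.get("frequencies", "empirical").strip().lower()
            if block.frequencies not in ("empirical", "uniform"):
                raise ConfigurationError(
                    f"[{sec}] frequencies must be empirical or uniform")
            block.features = _parse_list(kv.get("features", ""))
            block.exclude_features = _parse_list(kv.get("exclude_features", ""))
            if "minimum_coverage" in kv:
                try:
                    block.minimum_coverage = float(kv["minimum_coverage"])
                except ValueError:
                    raise ConfigurationError(
                        f"[{sec}] minimum_coverage must be a number")
                if not 0.0 <= block.minimum_coverage <= 1.0:
                    raise ConfigurationError(
                        f"[{sec}] minimum_coverage must be in [0, 1]")
            if "recode_borrowings" in kv:
                block.recode_borrowings = _parse_bool(
                    kv["recode_borrowings"], f"[{sec}] recode_borrowings")
            block.binarize = kv.get("binarize", "auto").strip().lower()
            if block.binarize not in ("auto", "always", "never"):
                raise ConfigurationError(f"[{sec}] unknown binarize mode")
            block.clock = kv.get("clock", "default").strip().lower()
            cfg.model_blocks.append(block)
        elif sec.startswith("clock ") or sec == "clock":
            name = sec[len("clock"):].strip() or "default"
            for key in kv:
                if key not in KNOWN_CLOCK_KEYS:
                    warnings.warn(f"[{sec}] ignoring unknown key {key!r}")
            kind = kv.get("type", "strict").strip().lower()
            if kind not in CLOCK_KINDS:
                raise ConfigurationError(f"[{sec}] unknown clock type {kind!r}")
            dist = None
            if kind == "relaxed":
                dist = kv.get("distribution", "lognormal").strip().lower()
                if dist not in RELAXED_DISTRIBUTIONS:
                    raise ConfigurationError(
                        f"[{sec}] unknown relaxed distribution {dist!r}")
            elif "distribution" in kv:
                raise ConfigurationError(
                    f"[{sec}] distribution is only valid for relaxed clocks")
            cfg.clock_blocks.append(ClockBlock(name, kind, dist))
        elif sec == "calibration":
            for clade, value in kv.items():
                lower, upper = parse_calibration_range(value)
                if lower < 0:
                    raise ConfigurationError("calibration ages must be >= 0")
                cfg.calibrations.append((clade, lower, upper))
        elif sec not in KNOWN_SECTIONS:
            warnings.warn(f"ignoring unknown section [{sec}]")

    if not cfg.model_blocks:
        raise ConfigurationError("configuration has no [model ...] section")
    clock_names = {c.name for c in cfg.clock_blocks}
    referenced = {b.clock for b in cfg.model_blocks}
    for missing in sorted(referenced - clock_names):
        if missing == "default":
            cfg.clock_blocks.append(ClockBlock("default", "strict"))
        else:
            raise ConfigurationError(
                f"model block references undefined clock {missing!r}")
    return cfg


def parse_config(text: str) -> AnalysisConfig:
    """Parse and validate a single configuration text."""
    return _build(_read_sections(text))


def merge_configs(texts: list[str]) -> AnalysisConfig:
    """Layer several configuration texts, later files overriding earlier
    ones at key level, then validate the merged result."""
    if not texts:
        raise ConfigurationError("merge_configs needs at least one text")
    return _build(_merge_sections([_read_sections(t) for t in texts]))


def render_config(cfg: AnalysisConfig) -> str:
    """Canonical INI rendering of a parsed config (round-trip stable)."""
    buf = io.StringIO()
    for sec in sorted(cfg.raw_sections):
        buf.write(f"[{sec}]\n")
        for key, value in cfg.raw_sections[sec].items():
            buf.write(f"{key} = {value}\n")
        buf.write("\n")
    return buf.getvalue()


def provenance_header(config_text: str, data_tables=(), version: str = "",
                      timestamp: str = "", embed_data: bool = False) -> str:
    """Comment block stamped at the top of every output file.

    Contains the verbatim configuration, the tool version and the run
    timestamp; with *embed_data* each referenced table is appended in its
    canonical serialisation, making the output self-contained.
    """
    lines = [f"# cognatree {version}".rstrip(),
             f"# run at {timestamp}".rstrip(),
             "# --- begin configuration ---"]
    lines += [f"# {ln}" for ln in config_text.splitlines()]
    lines.append("# --- end configuration ---")
    if embed_data:
        for table in data_tables:
            lines.append(f"# --- begin data {table.source} ---")
            lines += [f"# {ln}" for ln in table.write_matrix().splitlines()]
            lines.append(f"# --- end data {table.source} ---")
    return "\n".join(lines) + "\n"
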