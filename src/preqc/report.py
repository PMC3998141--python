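"""Pipeline orchestration, the versioned JSON report, and plotting.

``run_all`` executes every metric on a read set with a single global seed
fanned out to independent per-metric substreams (so disabling one metric
never perturbs another), collects the results into a schema-versioned,
JSON-serializable report, and records per-stage failures without aborting
the remaining stages. JSON output is byte-stable for a given input and seed:
keys are sorted and floats are serialized at 12 significant digits.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from . import __version__
from .branches import estimate_branch_rates
from .count_model import (
    estimate_genome_size,
    fit_mixture_em,
    sample_count_histogram,
)
from .index import KmerIndex
from .read_metrics import (
    gc_coverage_histogram,
    kmer_count_histogram_51,
    per_base_error_rate,
    quality_by_position,
)
from .seqio import ReadSet
from .walks import estimate_fragment_sizes, simulate_assembly

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"

ALL_METRICS = (
    "kmer_histogram_51",
    "genome_size",
    "gc_coverage",
    "branch_rates",
    "error_profile",
    "quality_profile",
    "fragment_sizes",
    "sim_assembly",
)


@dataclass
class PreqcConfig:
    """Run parameters; defaults are the full-scale sampling sizes, with
    ``scale`` shrinking every per-metric sample count for desk-scale runs."""

    seed: int = 1
    scale: float = 1.0
    k_genome_size: int = 31
    k_fixed_hist: int = 51
    branch_k_values: tuple = tuple(range(21, 72, 5))
    assembly_k_values: tuple = tuple(range(21, 92, 5))
    hist_reads: int = 50_000
    error_profile_reads: int = 100_000
    branch_reads: int = 1_000_000
    fragment_pairs: int = 100_000
    assembly_walks: int = 20_000
    quality_reads: int = 100_000
    gc_reads: int = 50_000
    metrics: tuple = ALL_METRICS

    def scaled(self, n: int) -> int:
        return max(1, int(round(n * self.scale)))


@dataclass
class PreqcReport:
    """JSON-serializable union of all metric outputs."""

    data: dict = field(default_factory=dict)

    @property
    def sections(self) -> dict:
        return self.data.setdefault("sections", {})

    @property
    def errors(self) -> list:
        return self.data.setdefault("errors", [])


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        if not np.isfinite(v):
            return None
        return float(f"{v:.12g}")
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _to_jsonable(obj.tolist())
    return obj


def run_all(reads: ReadSet, config: PreqcConfig | None = None) -> PreqcReport:
    """Build the index and run every configured metric; never aborts midway."""
    if len(reads) == 0:
        raise ValueError("cannot analyze an empty ReadSet")
    cfg = config or PreqcConfig()
    report = PreqcReport(
        {
            "schema_version": SCHEMA_VERSION,
            "tool_version": __version__,
            "parameters": _to_jsonable(asdict(cfg)),
            "sections": {},
            "errors": [],
        }
    )
    root = np.random.SeedSequence(cfg.seed)
    streams = {
        name: np.random.default_rng(s)
        for name, s in zip(ALL_METRICS, root.spawn(len(ALL_METRICS)))
    }

    index = None
    if {"kmer_histogram_51", "genome_size", "gc_coverage"} & set(cfg.metrics):
        index = KmerIndex(reads, [cfg.k_genome_size, cfg.k_fixed_hist])

    def stage(name, fn):
        if name not in cfg.metrics:
            return
        t0 = time.perf_counter()
        try:
            report.sections[name] = _to_jsonable(fn())
            logger.info("stage %s done in %.1fs", name, time.perf_counter() - t0)
        except Exception as exc:  # noqa: BLE001 - stage isolation by design
            logger.exception("stage %s failed", name)
            report.errors.append({"stage": name, "error": str(exc)})

    def _hist51():
        h = kmer_count_histogram_51(
            index,
            cfg.scaled(cfg.hist_reads),
            streams["kmer_histogram_51"],
            k=cfg.k_fixed_hist,
        )
        return {"k": h.k, "counts": {str(c): f for c, f in sorted(h.counts.items())},
                "n_sampled_reads": h.n_sampled_reads}

    stage("kmer_histogram_51", _hist51)

    def _genome_size():
        hist = sample_count_histogram(
            index, cfg.k_genome_size, cfg.scaled(cfg.hist_reads),
            streams["genome_size"],
        )
        model = fit_mixture_em(hist)
        est = estimate_genome_size(
            model, len(reads), reads.modal_read_length, cfg.k_genome_size
        )
        return {
            "G": est.G, "lambda": est.lambda_used, "w0": est.w0_used,
            "k": est.k_used, "n_reads": est.n_reads, "read_len": est.read_len,
            "mixture_model": {
                "lambda": model.lam, "lambda_e": model.lambda_e,
                "weights": model.weights,
                "log_likelihood_trace": model.log_likelihood_trace,
            },
        }

    stage("genome_size", _genome_size)

    def _gc():
        g = gc_coverage_histogram(
            index, cfg.k_fixed_hist, cfg.scaled(cfg.gc_reads),
            rng=streams["gc_coverage"],
        )
        return {"k": g.k, "gc_edges": g.gc_edges, "count_edges": g.count_edges,
                "matrix": g.matrix}

    stage("gc_coverage", _gc)

    def _branches():
        rates = estimate_branch_rates(
            reads, cfg.branch_k_values,
            n_reads=cfg.scaled(cfg.branch_reads),
            hist_reads=cfg.scaled(cfg.hist_reads),
            rng=streams["branch_rates"],
        )
        return {
            "entries": [
                {
                    "k": e.k, "N_h": e.N_h, "n_branches": e.n_branches,
                    "F_error": e.F_error, "F_variant": e.F_variant,
                    "F_repeat": e.F_repeat, "lambda": e.lam,
                    "variant_rate": e.variant_rate, "repeat_rate": e.repeat_rate,
                }
                for e in rates.entries
            ],
            "skipped": [[k, msg] for k, msg in rates.skipped],
        }

    stage("branch_rates", _branches)

    def _errors():
        prof = per_base_error_rate(
            reads, cfg.scaled(cfg.error_profile_reads),
            rng=streams["error_profile"],
        )
        return {"err": prof.err, "tot": prof.tot, "rate": prof.rate(),
                "n_sampled_reads": prof.n_sampled_reads}

    stage("error_profile", _errors)

    def _quality():
        q = quality_by_position(
            reads, cfg.scaled(cfg.quality_reads), streams["quality_profile"]
        )
        return {"mean": q.mean, "deciles": q.deciles,
                "n_sampled_reads": q.n_sampled_reads}

    stage("quality_profile", _quality)

    def _fragments():
        if not reads.paired:
            raise ValueError("read set is not paired")
        fsindex = KmerIndex(reads, [51])
        fs = estimate_fragment_sizes(
            fsindex, cfg.scaled(cfg.fragment_pairs), rng=streams["fragment_sizes"]
        )
        return {"lengths": fs.lengths, "n_attempted": fs.n_attempted,
                "n_resolved": fs.n_resolved, "mean": fs.mean(), "sd": fs.sd()}

    stage("fragment_sizes", _fragments)

    def _assembly():
        ws = simulate_assembly(
            reads, cfg.assembly_k_values,
            n_walks=cfg.scaled(cfg.assembly_walks),
            hist_reads=cfg.scaled(cfg.hist_reads),
            rng=streams["sim_assembly"],
        )
        return {
            "entries": [
                {"k": e.k, "n50": e.n50, "n_walks": e.n_walks, "lambda": e.lam,
                 "length_histogram": _length_histogram(e.lengths)}
                for e in ws.entries
            ],
            "skipped": [[k, msg] for k, msg in ws.skipped],
        }

    stage("sim_assembly", _assembly)
    return report


def _length_histogram(lengths, n_bins: int = 50):
    if not lengths:
        return {"edges": [], "counts": []}
    counts, edges = np.histogram(lengths, bins=min(n_bins, max(1, len(set(lengths)))))
    return {"edges": edges, "counts": counts}


def write_json(report: PreqcReport, path) -> None:
    payload = _to_jsonable(report.data)
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1, separators=(",", ": "))
        fh.write("\n")


def read_json(path) -> PreqcReport:
    with open(path) as fh:
        data = json.load(fh)
    version = data.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"report schema version {version!r} does not match "
            f"supported version {SCHEMA_VERSION!r}"
        )
    return PreqcReport(data)


# -- plotting -------------------------------------------------------------


def render_report(report: PreqcReport, path) -> None:
    """Render one panel per metric into a multi-page PDF.

    Sections missing from the report get an annotated empty panel; the
    report object itself is never modified.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.backends.backend_pdf import PdfPages

    sections = report.data.get("sections", {})

    def _empty(ax, name):
        ax.text(0.5, 0.5, f"{name}: not available", ha="center", va="center")
        ax.set_axis_off()

    with PdfPages(path) as pdf:
        def new_page(title):
            fig, ax = plt.subplots(figsize=(7, 5))
            ax.set_title(title)
            return fig, ax

        fig, ax = new_page("51-mer count histogram")
        sec = sections.get("kmer_histogram_51")
        if sec and sec.get("counts"):
            c = sorted(int(x) for x in sec["counts"])
            f = [sec["counts"][str(x)] for x in c]
            ax.plot(c, f, drawstyle="steps-mid")
            ax.set_xlabel("k-mer count")
            ax.set_ylabel("frequency")
            ax.set_yscale("log")
            ax.set_xlim(0, min(max(c), 200))
        else:
            _empty(ax, "kmer_histogram_51")
        pdf.savefig(fig); plt.close(fig)

        fig, ax = new_page("Variant branch rate vs k")
        sec = sections.get("branch_rates")
        if sec and sec.get("entries"):
            ks = [e["k"] for e in sec["entries"] if e["variant_rate"] is not None]
            vs = [e["variant_rate"] for e in sec["entries"] if e["variant_rate"] is not None]
            ax.plot(ks, vs, "o-")
            ax.set_xlabel("k"); ax.set_ylabel("variant branch rate")
            ax.set_yscale("log")
        else:
            _empty(ax, "branch_rates")
        pdf.savefig(fig); plt.close(fig)

        fig, ax = new_page("Repeat branch rate vs k")
        if sec and sec.get("entries"):
            ks = [e["k"] for e in sec["entries"] if e["repeat_rate"] is not None]
            rs = [e["repeat_rate"] for e in sec["entries"] if e["repeat_rate"] is not None]
            ax.plot(ks, rs, "o-")
            ax.set_xlabel("k"); ax.set_ylabel("repeat branch rate")
            ax.set_yscale("log")
        else:
            _empty(ax, "branch_rates")
        pdf.savefig(fig); plt.close(fig)

        fig, ax = new_page("Simulated contig N50 vs k")
        sec = sections.get("sim_assembly")
        if sec and sec.get("entries"):
            ax.plot([e["k"] for e in sec["entries"]],
                    [e["n50"] for e in sec["entries"]], "o-")
            ax.set_xlabel("k"); ax.set_ylabel("N50 (k-mers)")
        else:
            _empty(ax, "sim_assembly")
        pdf.savefig(fig); plt.close(fig)

        fig, ax = new_page("Per-position error rate")
        sec = sections.get("error_profile")
        if sec:
            rate = [r if r is not None else np.nan for r in sec["rate"]]
            ax.plot(rate)
            ax.set_xlabel("read position"); ax.set_ylabel("error rate")
        else:
            _empty(ax, "error_profile")
        pdf.savefig(fig); plt.close(fig)

        fig, ax = new_page("GC content vs k-mer count")
        sec = sections.get("gc_coverage")
        if sec:
            m = np.asarray(sec["matrix"], dtype=float)
            ax.imshow(np.log1p(m), aspect="auto", origin="lower",
                      extent=[1, m.shape[1] + 1, 0, 1])
            ax.set_xlabel("k-mer count"); ax.set_ylabel("GC fraction")
        else:
            _empty(ax, "gc_coverage")
        pdf.savefig(fig); plt.close(fig)

        fig, ax = new_page("Quality by position")
        sec = sections.get("quality_profile")
        if sec:
            mean = [m if m is not None else np.nan for m in sec["mean"]]
            ax.plot(mean, label="mean")
            dec = np.asarray(
                [[x if x is not None else np.nan for x in row]
                 for row in sec["deciles"]], dtype=float)
            if dec.size:
                ax.fill_between(range(dec.shape[1]), dec[0], dec[-1], alpha=0.3,
                                label="10th-90th pct")
            ax.set_xlabel("read position"); ax.set_ylabel("Phred score")
            ax.legend()
        else:
            _empty(ax, "quality_profile")
        pdf.savefig(fig); plt.close(fig)

        fig, ax = new_page("Fragment size distribution")
        sec = sections.get("fragment_sizes")
        if sec and sec.get("lengths"):
            ax.hist(sec["lengths"], bins=50)
            ax.set_xlabel("fragment size (bp)"); ax.set_ylabel("pairs")
        else:
            _empty(ax, "fragment_sizes")
        pdf.savefig(fig); plt.close(fig)
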