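"""Bundled per-biome profiler pipelines, expressed as scripts in the DSL.

Every biome pipeline runs preprocess (quality-25 trimming, discarding reads
shorter than 45 bp) → host-read removal for host-associated biomes (45 bp
minimum alignment length) → gene-catalog mapping → counting (eggNOG OGs,
KEGG KOs and raw gene abundances) → write.  The thresholds appear as plain
constants in the script text so users can edit them.
"""

from __future__ import annotations

from pathlib import Path

from .errors import NGLError, PreflightError
from .interpreter import RunReport, RuntimeConfig, preflight_check, run_script
from .lang.parser import parse
from .lang.typecheck import check_types
from .references import Registry

#: biome -> (catalog registry key, catalog module import, host registry key or None)
BIOMES = {
    "human-gut": ("igc", "igc", "hg19"),
    "marine": ("om-rgc", "om-rgc", None),
    "mouse-gut": ("mouse-gut", "mouse-gut", "mm10"),
    "pig-gut": ("pig-gut", "pig-gut", "sus-scrofa"),
    "dog-gut": ("dog-gut", "dog-gut", "canis-familiaris"),
}

_HOST_STAGE = '''
mapped_host = map(input, reference="{host}", mapper=ARGV[3])
mapped_host = select(mapped_host, min_match_size=45, action="unmatch", keep="unmapped")
input = as_reads(mapped_host)
'''

_TEMPLATE = '''ngless "1.0"
import "mocat" version "1.0"
import "{module}" version "1.0"

input = load_mocat_sample(ARGV[1])

input = preprocess(input) using |read|:
    read = substrim(read, min_quality=25)
    if len(read) < 45:
        discard
{host_stage}
mapped = map(input, reference="{catalog}", mapper=ARGV[3])
mapped = select(mapped, min_match_size=45, action="unmatch")

counts_og = count(mapped, features="OG", multiple="dist1")
write(counts_og, ofile=ARGV[2] + ".OG.tsv")
counts_ko = count(mapped, features="KO", multiple="dist1")
write(counts_ko, ofile=ARGV[2] + ".KO.tsv")
counts_genes = count(mapped, features="genes", multiple="dist1")
write(counts_genes, ofile=ARGV[2] + ".genes.tsv")
'''


def get_profiler_script(biome: str) -> str:
    """Script text of the bundled pipeline for ``biome``.

    The script takes three arguments: sample directory, output path prefix,
    and aligner name (``builtin``, ``bwa`` or ``minimap2``).
    """
    if biome not in BIOMES:
        raise NGLError(
            f"unknown biome {biome!r} (available: {', '.join(sorted(BIOMES))})")
    catalog, module, host = BIOMES[biome]
    host_stage = _HOST_STAGE.format(host=host) if host else ""
    return _TEMPLATE.format(module=module, catalog=catalog, host_stage=host_stage)


def run_profiler(sample_dir: str | Path, biome: str, output_dir: str | Path,
                 registry: Registry | str | Path, aligner: str = "builtin",
                 config: RuntimeConfig | None = None) -> RunReport:
    """Run the bundled biome pipeline on one sample directory.

    Writes ``<output_dir>/<sample>.OG.tsv``, ``.KO.tsv`` and ``.genes.tsv``,
    the QC report, and ``<output_dir>/<sample>.report.json``.
    """
    sample_dir = Path(sample_dir)
    output_dir = Path(output_dir)
    if not isinstance(registry, Registry):
        registry = Registry.load(registry)
    output_dir.mkdir(parents=True, exist_ok=True)
    script = check_types(parse(get_profiler_script(biome)))
    prefix = output_dir / sample_dir.name
    cli_args = [str(sample_dir), str(prefix), aligner]
    if config is None:
        config = RuntimeConfig(registry=registry)
    elif config.registry is None:
        config = RuntimeConfig(threads=config.threads, temp_dir=config.temp_dir,
                               seed=config.seed, registry=registry,
                               keep_intermediates=config.keep_intermediates)
    findings = preflight_check(script, cli_args, registry)
    if findings:
        raise PreflightError(findings)
    report = run_script(script, config, cli_args)
    report_path = output_dir / f"{sample_dir.name}.report.json"
    report_path.write_text(report.to_json())
    report.outputs.append(report_path)
    return report
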