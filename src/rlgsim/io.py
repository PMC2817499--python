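"""File formats and run configuration.

All tables are plain TSV with one header line; lines starting with ``#``
echo the run configuration (gel windows, tolerances, seeds, config hash) so
every output is self-describing and byte-identical across reruns.  Genomes
are FASTA (one record per chromosome, one file per haplotype); methylation
overlays are BED-like TSV (chrom, start, end, state; 0-based half-open).
Locus keys are ``chrom:landmark_cut:direction``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .compare import MethylationCall, SpotMatch
from .enzymes import (
    BUILTIN_ENZYMES,
    Enzyme,
    Haplotype,
    MethylationState,
    _matches_at,
)
from .gel import GelModel, RlgsFragment, Spot, SpotPattern
from .segregation import SegregationResult
from .simulate import Fixture


# --- genomes and overlays ---------------------------------------------------

def read_fasta(path) -> Dict[str, str]:
    """Read chromosome sequences from FASTA; empty files give empty genomes."""
    sequences: Dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"{path}: duplicate chromosome id {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    return sequences


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_overlay(path) -> Dict[Tuple[str, int], MethylationState]:
    """Read a BED-like methylation overlay (chrom, start, end, state)."""
    overlay: Dict[Tuple[str, int], MethylationState] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(
                    f"{path}, line {lineno}: expected 4 tab-separated columns "
                    "(chrom, start, end, state)"
                )
            chrom, start_s, end_s, state_s = parts[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(
                    f"{path}, line {lineno}: non-integer coordinates"
                ) from None
            if not 0 <= start < end:
                raise ValueError(
                    f"{path}, line {lineno}: need 0 <= start < end (half-open)"
                )
            try:
                state = MethylationState(state_s)
            except ValueError:
                raise ValueError(
                    f"{path}, line {lineno}: unknown methylation state {state_s!r}"
                ) from None
            overlay[(chrom, start)] = state
    return overlay


def write_overlay(
    hap: Haplotype, path, enzymes: Optional[Iterable[Enzyme]] = None
) -> None:
    enzymes = list(enzymes) if enzymes else list(BUILTIN_ENZYMES.values())
    rows = []
    for (chrom, start), state in sorted(hap.overlay.items()):
        seq = hap.sequences[chrom]
        width = next(
            (len(e.recognition) for e in enzymes if _matches_at(seq, start, e)), 1
        )
        rows.append(f"{chrom}\t{start}\t{start + width}\t{state.value}")
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))


def load_haplotype(
    hap_id: str,
    fasta_path,
    overlay_path=None,
    enzymes: Optional[Iterable[Enzyme]] = None,
) -> Haplotype:
    """Load and validate one haplotype from FASTA + optional overlay."""
    overlay = read_overlay(overlay_path) if overlay_path else {}
    hap = Haplotype(id=hap_id, sequences=read_fasta(fasta_path), overlay=overlay)
    return hap.validate(enzymes or ())


# --- run configuration ------------------------------------------------------

@dataclass
class RunConfig:
    """Serializable run parameters, echoed into every output."""

    window_1d: Tuple[int, int] = (500, 25_000)
    window_2d: Tuple[int, int] = (100, 5_000)
    merge_tol: float = 0.01
    match_tol: float = 0.01
    ratio_tol: float = 0.1
    alpha: float = 0.05
    correction: str = "bh"
    seed: int = 0
    include_sequence_end: bool = False
    include_diagonal: bool = True

    @property
    def gel(self) -> GelModel:
        return GelModel(tuple(self.window_1d), tuple(self.window_2d))

    def to_dict(self) -> Dict[str, object]:
        d = asdict(self)
        d["window_1d"] = list(self.window_1d)
        d["window_2d"] = list(self.window_2d)
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def to_file(self, path) -> None:
        lines = []
        for key, value in self.to_dict().items():
            if isinstance(value, list):
                value = ",".join(str(v) for v in value)
            lines.append(f"{key} = {value}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kwargs: Dict[str, object] = {}
        defaults = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}, line {lineno}: expected 'key = value'")
                key, _, raw = line.partition("=")
                key, raw = key.strip(), raw.strip()
                if not hasattr(defaults, key):
                    raise ValueError(f"{path}, line {lineno}: unknown key {key!r}")
                default = getattr(defaults, key)
                if isinstance(default, tuple):
                    kwargs[key] = tuple(int(v) for v in raw.split(","))
                elif isinstance(default, bool):
                    kwargs[key] = raw.lower() in ("1", "true", "yes")
                elif isinstance(default, int):
                    kwargs[key] = int(raw)
                elif isinstance(default, float):
                    kwargs[key] = float(raw)
                else:
                    kwargs[key] = raw
        return cls(**kwargs)


def _echo_lines(config: Optional[RunConfig], extra: Mapping[str, object] = ()) -> str:
    lines = []
    if config is not None:
        lines.append(f"# config_hash={config.config_hash}")
        for key, value in config.to_dict().items():
            if isinstance(value, list):
                value = ",".join(str(v) for v in value)
            lines.append(f"# {key}={value}")
    for key, value in dict(extra).items():
        lines.append(f"# {key}={value}")
    return "".join(line + "\n" for line in lines)


# --- spot and fragment tables -----------------------------------------------

def _format_loci(loci: Sequence[Tuple[str, int, str, str]]) -> str:
    return ";".join(f"{c}:{cut}:{d}:{h}" for c, cut, d, h in loci)


def _parse_loci(text: str) -> Tuple[Tuple[str, int, str, str], ...]:
    out = []
    for token in str(text).split(";"):
        chrom, cut, direction, hap = token.rsplit(":", 3)
        out.append((chrom, int(cut), direction, hap))
    return tuple(out)


def write_spot_table(
    pattern: SpotPattern, path, config: Optional[RunConfig] = None
) -> None:
    gel = pattern.gel
    header = _echo_lines(
        config,
        {
            "gel_window_1d": f"{gel.window_1d[0]},{gel.window_1d[1]}",
            "gel_window_2d": f"{gel.window_2d[0]},{gel.window_2d[1]}",
        },
    )
    df = pd.DataFrame(
        [
            {
                "sample_id": pattern.sample_id,
                "combo": pattern.combo,
                "x1": s.x1,
                "x2": s.x2,
                "len_1d": s.len_1d,
                "len_2d": s.len_2d,
                "intensity": s.intensity,
                "loci": _format_loci(s.loci),
            }
            for s in pattern.spots
        ],
        columns=["sample_id", "combo", "x1", "x2", "len_1d", "len_2d", "intensity", "loci"],
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def read_spot_table(path) -> SpotPattern:
    """Re-read a spot table; spots, intensities and ordering round-trip exactly."""
    windows = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, raw = line[1:].strip().partition("=")
            if key in ("gel_window_1d", "gel_window_2d"):
                windows[key] = tuple(int(v) for v in raw.split(","))
    gel = GelModel(
        windows.get("gel_window_1d", (500, 25_000)),
        windows.get("gel_window_2d", (100, 5_000)),
    )
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    spots = [
        Spot(
            x1=float(r.x1),
            x2=float(r.x2),
            len_1d=int(r.len_1d),
            len_2d=int(r.len_2d),
            intensity=float(r.intensity),
            loci=_parse_loci(r.loci),
        )
        for r in df.itertuples()
    ]
    if df.empty:
        sample_id, combo = Path(path).stem, ""
    else:
        sample_id, combo = str(df.sample_id.iloc[0]), str(df.combo.iloc[0])
    return SpotPattern(sample_id=sample_id, combo=combo, spots=spots, gel=gel)


def write_fragment_table(
    fragments: Sequence[RlgsFragment], path, config: Optional[RunConfig] = None
) -> None:
    df = pd.DataFrame(
        [
            {
                "chrom": f.chrom,
                "landmark_cut": f.landmark_cut,
                "direction": f.direction,
                "len_1d": f.len_1d,
                "end_1d_kind": f.end_1d_kind,
                "len_2d": f.len_2d,
                "end_2d_kind": f.end_2d_kind,
                "haplotype": f.haplotype_id,
            }
            for f in fragments
        ],
        columns=[
            "chrom", "landmark_cut", "direction", "len_1d", "end_1d_kind",
            "len_2d", "end_2d_kind", "haplotype",
        ],
    )
    with open(path, "w") as fh:
        fh.write(_echo_lines(config))
        df.to_csv(fh, sep="\t", index=False)


def write_diff_table(
    matches: Sequence[SpotMatch],
    calls: Sequence[MethylationCall],
    path,
    config: Optional[RunConfig] = None,
) -> None:
    calls_by_locus = {c.locus: c for c in calls}
    rows = []
    for m in matches:
        call = calls_by_locus.get(m.key)
        rows.append(
            {
                "locus": m.key,
                "status": m.status,
                "intensity_a": m.a.intensity if m.a else 0.0,
                "intensity_b": m.b.intensity if m.b else 0.0,
                "intensity_ratio": "" if m.intensity_ratio is None else m.intensity_ratio,
                "call": call.call if call else "",
                "zygosity": (call.zygosity or "") if call else "",
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["locus", "status", "intensity_a", "intensity_b",
                 "intensity_ratio", "call", "zygosity"],
    )
    with open(path, "w") as fh:
        fh.write(_echo_lines(config))
        df.to_csv(fh, sep="\t", index=False)


def write_segregation_table(
    results: Sequence[SegregationResult], path, config: Optional[RunConfig] = None
) -> None:
    def fmt(mapping: Mapping) -> str:
        return ";".join(f"{k.value}:{v}" for k, v in sorted(mapping.items(), key=lambda kv: kv[0].value))

    df = pd.DataFrame(
        [
            {
                "locus": r.locus,
                "combo": r.combo,
                "generation": r.generation,
                "n": sum(r.observed.values()),
                "observed": fmt(r.observed),
                "expected": fmt(r.expected),
                "test": r.test,
                "p": r.p_value,
                "p_adj": r.p_adjusted,
                "verdict": r.verdict,
                "n_other": r.n_other,
            }
            for r in results
        ],
        columns=["locus", "combo", "generation", "n", "observed", "expected",
                 "test", "p", "p_adj", "verdict", "n_other"],
    )
    with open(path, "w") as fh:
        fh.write(_echo_lines(config))
        df.to_csv(fh, sep="\t", index=False)


# --- fixture writer ---------------------------------------------------------

def write_fixture(fixture: Fixture, outdir) -> Dict[str, str]:
    """Write the fixture to files so downstream stages run from disk alone.

    Emits one FASTA and one overlay per parental haplotype, a per-individual
    overlay for every simulated progeny (sequences are referenced from the
    parental FASTA they were inherited from), and a panel manifest TSV.
    Returns a mapping of logical names to written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: Dict[str, str] = {}
    hap_files: Dict[str, str] = {}
    for parent in (fixture.parent_n, fixture.parent_k):
        for hap in parent.haplotypes:
            fasta = outdir / f"{hap.id}.fasta"
            overlay = outdir / f"{hap.id}.overlay.tsv"
            write_fasta(hap.sequences, fasta)
            write_overlay(hap, overlay)
            hap_files[hap.id] = fasta.name
            written[f"fasta:{hap.id}"] = str(fasta)
            written[f"overlay:{hap.id}"] = str(overlay)
    rows = []
    for panel_name, panel in fixture.panels.items():
        for ind in panel.individuals:
            entry = {"individual": ind.id, "panel": panel_name,
                     "mother": panel.mother_id, "father": panel.father_id,
                     "model": panel.model.name, "seed": panel.seed}
            for slot, hap in zip(("hap1", "hap2"), ind.haplotypes):
                overlay_path = outdir / f"{ind.id}.{slot}.overlay.tsv"
                write_overlay(hap, overlay_path)
                entry[f"{slot}_fasta"] = hap_files[hap.meta["source_hap"]]
                entry[f"{slot}_overlay"] = overlay_path.name
            rows.append(entry)
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    written["manifest"] = str(manifest)
    return written
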