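"""Local BAM slicing, a GDC-style slicing client, and manifest modeling.

Cohort repositories such as the NCI Genomic Data Commons expose a BAM-slicing
REST endpoint that returns only the alignments overlapping requested regions,
so a study of a handful of loci never downloads whole BAM files. This module
models the file metadata (project / experimental strategy / alignment
workflow), slices local BAMs with the same overlap semantics, and downloads
remote slices authenticated by a token file (``gdc_token``).
"""

from __future__ import annotations

import json
import logging
import tempfile
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import pysam

from .errors import (
    AuthConfigurationError,
    ContigError,
    DownloadIntegrityError,
    ManifestError,
    MissingIndexError,
)
from .regions import GenomicInterval, format_region

logger = logging.getLogger(__name__)

EXPERIMENTAL_STRATEGIES = ("RNA-Seq", "WGS", "WXS")
REFERENCE_SPACES = ("genomic", "transcriptome")

# BGZF end-of-file marker every intact BAM must end with
BGZF_EOF = bytes.fromhex(
    "1f8b08040000000000ff0600424302001b0003000000000000000000"
)


@dataclass(frozen=True)
class BamFileRecord:
    """Metadata for one BAM file in a slicing manifest."""

    file_id: str
    patient_id: str
    sample_type: str
    experimental_strategy: str
    workflow: str
    reference_space: str = "genomic"
    location: str = ""

    def __post_init__(self):
        if self.experimental_strategy not in EXPERIMENTAL_STRATEGIES:
            raise ManifestError(
                f"experimental_strategy {self.experimental_strategy!r} not in "
                f"{EXPERIMENTAL_STRATEGIES}"
            )
        if self.reference_space not in REFERENCE_SPACES:
            raise ManifestError(
                f"reference_space {self.reference_space!r} not in {REFERENCE_SPACES}"
            )


@dataclass
class SliceManifest:
    """The BAM files selected for slicing within one project."""

    project_id: str
    records: list[BamFileRecord] = field(default_factory=list)
    query_time: str = ""

    def __post_init__(self):
        if not self.query_time:
            self.query_time = datetime.now(timezone.utc).isoformat()
        ids = [r.file_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ManifestError(f"duplicate file ids in manifest: {dupes}")

    def to_tsv(self, path) -> None:
        pd.DataFrame([asdict(r) for r in self.records]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path, project_id: str) -> "SliceManifest":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        return cls(project_id, [BamFileRecord(**row) for row in df.to_dict("records")])


# ---------------------------------------------------------------------------
# Catalogs (local record lists or a remote endpoint)
# ---------------------------------------------------------------------------

class LocalCatalog:
    """A project catalog backed by in-memory records or a TSV file."""

    def __init__(self, records: Iterable[Mapping]):
        self._records = [dict(r) for r in records]

    @classmethod
    def from_tsv(cls, path) -> "LocalCatalog":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        return cls(df.to_dict("records"))

    def files(self) -> list[dict]:
        return [dict(r) for r in self._records]


class RemoteCatalog:
    """A catalog served by a GDC-style REST endpoint (``GET <base>/files``)."""

    def __init__(self, base_url: str, timeout: float = 10.0):
        self.base_url = base_url.rstrip("/")
        self.timeout = timeout

    def files(self) -> list[dict]:
        with urllib.request.urlopen(
            f"{self.base_url}/files", timeout=self.timeout
        ) as resp:
            return json.loads(resp.read().decode())


def _dedupe_keep_order(values: Iterable[str]) -> list[str]:
    seen, out = set(), []
    for v in values:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


@dataclass(frozen=True)
class CatalogSummary:
    projects: tuple[str, ...]
    strategies: tuple[str, ...]
    workflows: tuple[str, ...]


def query_available(catalog) -> CatalogSummary:
    """Distinct project ids, experimental strategies and workflows on offer."""
    files = catalog.files()
    return CatalogSummary(
        projects=tuple(_dedupe_keep_order(f["project_id"] for f in files)),
        strategies=tuple(_dedupe_keep_order(f["experimental_strategy"] for f in files)),
        workflows=tuple(_dedupe_keep_order(f["workflow"] for f in files)),
    )


def build_manifest(
    project_id: str, strategy: str, workflow: str, catalog
) -> SliceManifest:
    """Select the catalog entries matching all three selectors.

    An empty selection yields an empty manifest with a logged warning, not an
    error, so cohort scripts can proceed across projects.
    """
    records = []
    for f in catalog.files():
        if (
            f["project_id"] == project_id
            and f["experimental_strategy"] == strategy
            and f["workflow"] == workflow
        ):
            records.append(
                BamFileRecord(
                    file_id=f["file_id"],
                    patient_id=f.get("patient_id", ""),
                    sample_type=f.get("sample_type", ""),
                    experimental_strategy=f["experimental_strategy"],
                    workflow=f["workflow"],
                    reference_space=f.get("reference_space", "genomic"),
                    location=f.get("location", ""),
                )
            )
    if not records:
        logger.warning(
            "no catalog entries match project=%s strategy=%s workflow=%s",
            project_id, strategy, workflow,
        )
    return SliceManifest(project_id, records)


# ---------------------------------------------------------------------------
# Local slicing
# ---------------------------------------------------------------------------

def slice_local(
    bam_path, regions: Sequence[GenomicInterval], out_path
) -> str:
    """Extract reads whose alignment span overlaps any region into a new BAM.

    Overlap means reference-span overlap of the alignment (soft clips carry
    no reference span); reads overlapping several regions are written once.
    The original header is preserved and the output is coordinate-sorted and
    indexed. Returns the output path.
    """
    bam_path, out_path = str(bam_path), str(out_path)
    with pysam.AlignmentFile(bam_path) as bam:
        try:
            bam.check_index()
        except (ValueError, AttributeError) as exc:
            raise MissingIndexError(f"BAM index required for {bam_path}") from exc
        for r in regions:
            if r.contig not in bam.references:
                raise ContigError(
                    f"contig {r.contig!r} absent from BAM header of {bam_path}"
                )
        seen: set[tuple] = set()
        with tempfile.NamedTemporaryFile(suffix=".bam", delete=False) as tmp:
            tmp_path = tmp.name
        try:
            with pysam.AlignmentFile(tmp_path, "wb", template=bam) as out:
                for r in regions:
                    for read in bam.fetch(r.contig, r.start - 1, r.end):
                        key = (read.query_name, read.flag, read.reference_id,
                               read.reference_start, read.cigarstring)
                        if key in seen:
                            continue
                        seen.add(key)
                        out.write(read)
            pysam.sort("-o", out_path, tmp_path)
            pysam.index(out_path)
        finally:
            Path(tmp_path).unlink(missing_ok=True)
    return out_path


# ---------------------------------------------------------------------------
# Remote slicing client
# ---------------------------------------------------------------------------

def read_token(token_path) -> str:
    """Read and validate the access token file (conventionally ``gdc_token``)."""
    p = Path(token_path)
    if p.is_dir():
        p = p / "gdc_token"
    if not p.exists():
        raise AuthConfigurationError(f"token file not found: {p}")
    token = p.read_text().strip()
    if not token:
        raise AuthConfigurationError(f"token file is empty: {p}")
    return token


def bam_is_intact(path) -> bool:
    """Cheap integrity check: BGZF magic at start and EOF marker at end."""
    p = Path(path)
    if not p.exists() or p.stat().st_size < len(BGZF_EOF) + 2:
        return False
    data = p.read_bytes()
    return data[:2] == b"\x1f\x8b" and data.endswith(BGZF_EOF)


def download_sliced(
    manifest: SliceManifest,
    regions: Sequence[GenomicInterval],
    token_path,
    out_dir,
    endpoint: Optional[str] = None,
    retries: int = 3,
    timeout: float = 30.0,
) -> pd.DataFrame:
    """Download one sliced BAM per manifest record from a slicing endpoint.

    The token is read (and validated) before any request. Regions are passed
    as repeated ``region`` query parameters; the token travels in the
    ``X-Auth-Token`` header, mirroring the GDC BAM-slicing API. Existing
    intact output files are kept untouched, making re-runs idempotent.
    Failures are retried ``retries`` times and then recorded — never
    silently dropped. Returns a report table with columns
    (file_id, status, bytes, attempts, path); statuses are ``ok``,
    ``cached``, ``auth_error``, ``http_error``, ``transport_error`` and
    ``integrity_error``.
    """
    token = read_token(token_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    qs = "&".join(
        f"region={urllib.parse.quote(format_region(r))}" for r in regions
    )
    report = []
    for rec in manifest.records:
        base = (endpoint or rec.location).rstrip("/")
        url = f"{base}/slicing/view/{rec.file_id}?{qs}"
        dest = out_dir / f"{rec.file_id}.bam"
        if bam_is_intact(dest):
            report.append({"file_id": rec.file_id, "status": "cached",
                           "bytes": dest.stat().st_size, "attempts": 0,
                           "path": str(dest)})
            continue
        status, nbytes, attempts = "transport_error", 0, 0
        for attempt in range(1, retries + 1):
            attempts = attempt
            req = urllib.request.Request(url, headers={"X-Auth-Token": token})
            try:
                with urllib.request.urlopen(req, timeout=timeout) as resp:
                    body = resp.read()
            except urllib.error.HTTPError as exc:
                status = "auth_error" if exc.code in (401, 403) else "http_error"
                break  # auth/HTTP errors are not transient: no retry
            except (urllib.error.URLError, OSError):
                status = "transport_error"
                continue
            dest.write_bytes(body)
            nbytes = len(body)
            if bam_is_intact(dest):
                status = "ok"
            else:
                dest.unlink(missing_ok=True)
                status = "integrity_error"
            break
        report.append({"file_id": rec.file_id, "status": status,
                       "bytes": nbytes, "attempts": attempts,
                       "path": str(dest) if status in ("ok", "cached") else ""})
    return pd.DataFrame(report, columns=["file_id", "status", "bytes", "attempts", "path"])


def match_timepoints(manifest: SliceManifest) -> dict[str, list[BamFileRecord]]:
    """Group records by patient, keeping only matched multi-condition subjects.

    A patient is kept iff they have at least two records differing in
    sample_type or experimental_strategy (e.g. primary vs post-treatment, or
    RNA-Seq vs WGS of the same subject). Groups are returned in patient-id
    order; records within a group keep manifest order.
    """
    groups: dict[str, list[BamFileRecord]] = {}
    for rec in manifest.records:
        groups.setdefault(rec.patient_id, []).append(rec)
    out: dict[str, list[BamFileRecord]] = {}
    for pid in sorted(groups):
        recs = groups[pid]
        conditions = {(r.sample_type, r.experimental_strategy) for r in recs}
        if len(recs) >= 2 and len(conditions) >= 2:
            out[pid] = recs
    return out
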