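"""Readers and writers for the formats the pipeline touches.

Spectra travel either as a columnar TSV (tab-separated, UTF-8, ``#``
comments; columns ``scan``, ``mz``, ``intensity`` with a sidecar metadata
table, or a bare two-column file for a single anonymous spectrum) or as a
subset of the mzXML interchange container: a scan list with base64-encoded
network-order float64 m/z-intensity pairs plus ``nameValue`` elements for
acquisition metadata.  Both round-trip losslessly (float64 in mzXML, 10
significant digits in TSV).

Tables (feature matrix, quantification, phenotype, results) are plain TSV
through pandas.  The shared configuration is a flat ``key = value`` file.
"""

from __future__ import annotations

import base64
import logging
import struct
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .core import FeatureMatrix, PipelineError, QuantTable, Spectrum

logger = logging.getLogger("icmprofile")

MZXML_NS = "http://sashimi.sourceforge.net/schema_revision/mzXML_3.2"

_META_FIELDS = ("animal", "group", "ejaculate", "spot", "acquisition")
_INT_META = ("ejaculate", "spot", "acquisition")


# --------------------------------------------------------------------------
# spectra

def _ensure_ascending(mz: np.ndarray, intensity: np.ndarray, label: str):
    if np.any(np.diff(mz) <= 0):
        order = np.argsort(mz, kind="stable")
        logger.warning("%s: m/z not strictly ascending; re-sorted", label)
        return mz[order], intensity[order]
    return mz, intensity


def _meta_from_strings(d: dict) -> dict:
    meta = {}
    for key in _META_FIELDS:
        if key in d and d[key] != "":
            meta[key] = int(d[key]) if key in _INT_META else d[key]
    if d.get("history"):
        meta["history"] = [h for h in str(d["history"]).split("|") if h]
    return meta


def write_spectra_tsv(spectra: list[Spectrum], path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# icmprofile spectra v1\n")
        fh.write("scan\tmz\tintensity\n")
        for i, s in enumerate(spectra):
            for mz, inten in zip(s.mz, s.intensity):
                fh.write(f"{i}\t{mz:.10g}\t{inten:.10g}\n")
    meta = pd.DataFrame(
        [
            {
                "scan": i,
                **{k: s.meta[k] for k in _META_FIELDS},
                "history": "|".join(s.meta["history"]),
            }
            for i, s in enumerate(spectra)
        ],
        columns=["scan", *_META_FIELDS, "history"],
    )
    meta.to_csv(path.with_suffix(path.suffix + ".meta.tsv"), sep="\t", index=False)


def read_spectra_tsv(path) -> list[Spectrum]:
    path = Path(path)
    if path.stat().st_size == 0:
        raise PipelineError(f"{path}: empty spectra file")
    try:
        frame = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        raise PipelineError(f"{path}: empty spectra file") from None
    # drop a header row if present
    if frame.iloc[0].str.contains("mz", case=False).any():
        frame = frame.iloc[1:]
    ncol = frame.shape[1]
    if ncol == 2:
        try:
            mz = frame[0].astype(float).to_numpy()
            inten = frame[1].astype(float).to_numpy()
        except ValueError as exc:
            raise PipelineError(f"{path}: unparsable numeric column ({exc})") from None
        mz, inten = _ensure_ascending(mz, inten, str(path))
        return [Spectrum(mz=mz, intensity=inten)]
    if ncol != 3:
        raise PipelineError(f"{path}: expected 2 or 3 columns, found {ncol}")
    try:
        scans = frame[0].astype(int).to_numpy()
        mz = frame[1].astype(float).to_numpy()
        inten = frame[2].astype(float).to_numpy()
    except ValueError as exc:
        raise PipelineError(f"{path}: unparsable column ({exc})") from None

    meta_path = path.with_suffix(path.suffix + ".meta.tsv")
    metas: dict[int, dict] = {}
    if meta_path.exists():
        mframe = pd.read_csv(meta_path, sep="\t", dtype=str).fillna("")
        for _, row in mframe.iterrows():
            metas[int(row["scan"])] = _meta_from_strings(row.to_dict())

    spectra = []
    for scan in np.unique(scans):
        mask = scans == scan
        smz, sint = _ensure_ascending(mz[mask], inten[mask], f"{path} scan {scan}")
        spectra.append(Spectrum(mz=smz, intensity=sint, meta=metas.get(int(scan), {})))
    return spectra


def _encode_peaks(s: Spectrum) -> str:
    interleaved = np.empty(2 * len(s), dtype=">f8")
    interleaved[0::2] = s.mz
    interleaved[1::2] = s.intensity
    return base64.b64encode(interleaved.tobytes()).decode("ascii")


def write_spectra_mzxml(spectra: list[Spectrum], path) -> None:
    root = etree.Element("mzXML", nsmap={None: MZXML_NS})
    run = etree.SubElement(root, "msRun", scanCount=str(len(spectra)))
    for i, s in enumerate(spectra, start=1):
        scan = etree.SubElement(
            run,
            "scan",
            num=str(i),
            msLevel="1",
            peaksCount=str(len(s)),
            lowMz=f"{s.mz[0]:.10g}",
            highMz=f"{s.mz[-1]:.10g}",
        )
        for key in _META_FIELDS:
            etree.SubElement(scan, "nameValue", name=key, value=str(s.meta[key]))
        etree.SubElement(
            scan, "nameValue", name="history", value="|".join(s.meta["history"])
        )
        peaks = etree.SubElement(
            scan,
            "peaks",
            precision="64",
            byteOrder="network",
            contentType="m/z-int",
            compressionType="none",
        )
        peaks.text = _encode_peaks(s)
    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def read_spectra_mzxml(path) -> list[Spectrum]:
    path = Path(path)
    if path.stat().st_size == 0:
        raise PipelineError(f"{path}: empty mzXML file")
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise PipelineError(f"{path}: malformed XML ({exc})") from None
    ns = {"m": MZXML_NS}
    scans = tree.findall(".//m:scan", ns)
    if not scans and tree.findall(".//scan"):
        scans = tree.findall(".//scan")
        ns = None
    spectra = []
    for scan in scans:
        num = scan.get("num", "?")
        peaks_el = scan.find("m:peaks", ns) if ns else scan.find("peaks")
        if peaks_el is None or not (peaks_el.text or "").strip():
            raise PipelineError(f"{path}: scan {num} has no peaks element")
        raw = base64.b64decode(peaks_el.text)
        n = len(raw) // 8
        if n % 2 or 8 * n != len(raw):
            raise PipelineError(f"{path}: scan {num} has a ragged peak array")
        data = np.array(struct.unpack(f">{n}d", raw))
        mz, inten = data[0::2], data[1::2]
        meta_raw = {}
        nv = scan.findall("m:nameValue", ns) if ns else scan.findall("nameValue")
        for el in nv:
            meta_raw[el.get("name")] = el.get("value", "")
        mz, inten = _ensure_ascending(mz, inten, f"{path} scan {num}")
        spectra.append(Spectrum(mz=mz, intensity=inten, meta=_meta_from_strings(meta_raw)))
    if not spectra:
        # a valid container with zero scans is a legitimate (empty) result
        run = tree.find(".//m:msRun", ns) if ns else tree.find(".//msRun")
        if run is None:
            raise PipelineError(f"{path}: no msRun element found")
    return spectra


def write_spectra(spectra: list[Spectrum], path, format: str = "tsv") -> None:
    """Write spectra as ``tsv`` or ``mzxml`` (subset)."""
    if format == "tsv":
        write_spectra_tsv(spectra, path)
    elif format == "mzxml":
        write_spectra_mzxml(spectra, path)
    else:
        raise PipelineError(f"unknown spectra format {format!r}")


def read_spectra(path, format: str | None = None) -> list[Spectrum]:
    """Read spectra; the format is inferred from the extension when omitted."""
    path = Path(path)
    if not path.exists():
        raise PipelineError(f"{path}: no such file")
    if format is None:
        format = "mzxml" if path.suffix.lower() in (".mzxml", ".xml") else "tsv"
    if format == "tsv":
        return read_spectra_tsv(path)
    if format == "mzxml":
        return read_spectra_mzxml(path)
    raise PipelineError(f"unknown spectra format {format!r}")


# --------------------------------------------------------------------------
# tables

def write_feature_matrix(m: FeatureMatrix, path) -> None:
    out = pd.concat([m.meta, m.values], axis=1)
    out.insert(0, "sample", out.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_feature_matrix(path) -> FeatureMatrix:
    frame = pd.read_csv(path, sep="\t", comment="#")
    meta_cols = ["sample", "animal", "group", "ejaculate", "spot", "acquisition"]
    missing = [c for c in meta_cols if c not in frame.columns]
    if missing:
        raise PipelineError(f"{path}: missing feature-matrix columns {missing}")
    frame = frame.set_index("sample")
    meta = frame[meta_cols[1:]].copy()
    values = frame.drop(columns=meta_cols[1:])
    bins = np.array([float(c) for c in values.columns])
    return FeatureMatrix(values=values.astype(float), bins=bins, meta=meta)


def write_quant_table(q: QuantTable, prefix) -> None:
    prefix = Path(prefix)
    q.proteins.to_csv(prefix.with_suffix(".proteins.tsv"), sep="\t")
    for which, frame in (("counts", q.counts), ("intensities", q.intensities)):
        flat = frame.copy()
        flat.columns = [f"{a}|{r}" for a, r in frame.columns]
        flat.to_csv(prefix.with_suffix(f".{which}.tsv"), sep="\t")
    q.groups.to_frame().to_csv(prefix.with_suffix(".groups.tsv"), sep="\t")


def read_quant_table(prefix) -> QuantTable:
    prefix = Path(prefix)
    proteins = pd.read_csv(prefix.with_suffix(".proteins.tsv"), sep="\t", index_col=0)
    proteins["cluster"] = proteins["cluster"].astype(str)
    frames = {}
    for which in ("counts", "intensities"):
        flat = pd.read_csv(prefix.with_suffix(f".{which}.tsv"), sep="\t", index_col=0)
        cols = pd.MultiIndex.from_tuples(
            [tuple(c.split("|", 1)) for c in flat.columns], names=["animal", "replicate"]
        )
        flat.columns = cols
        frames[which] = flat.astype(float)
    groups = pd.read_csv(prefix.with_suffix(".groups.tsv"), sep="\t", index_col=0)["group"]
    return QuantTable(
        proteins=proteins,
        counts=frames["counts"],
        intensities=frames["intensities"],
        groups=groups,
    )


def write_phenotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# --------------------------------------------------------------------------
# configuration

DEFAULT_CONFIG = {
    "snr_min": 2.0,
    "detect_half_window": 20,
    "bin_tolerance_ppm": 500.0,
    "annotation_tolerance_ppm": 500.0,
    "corr_min": 0.40,
    "corr_max": 0.90,
    "corr_step": 0.05,
    "min_keep_fraction": 0.5,
    "p_cut": 0.05,
    "fc_low": 0.66,
    "fc_high": 1.5,
    "gelc_fc_low": 0.71,
    "gelc_fc_high": 1.4,
    "nws_floor": 5.0,
    "tophat_half_window": 75,
    "sg_window": 21,
    "sg_order": 3,
    "align_top_n": 10,
    "align_match_ppm": 2000.0,
    "lockmass_mz": 7983.457,
    "lockmass_window_low": 5000.0,
    "lockmass_window_high": 12000.0,
}


def load_config(path=None) -> dict:
    """Load the flat ``key = value`` config, falling back to defaults."""
    cfg = dict(DEFAULT_CONFIG)
    if path is None:
        return cfg
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise PipelineError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in cfg:
            raise PipelineError(f"{path}:{lineno}: unknown configuration key {key!r}")
        kind = type(DEFAULT_CONFIG[key])
        cfg[key] = kind(value)
    return cfg


def save_config(cfg: dict, path) -> None:
    lines = [f"{key} = {cfg[key]}" for key in sorted(cfg)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
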