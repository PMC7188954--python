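"""RDML and plain-text fixture I/O.

RDML (Real-time PCR Data Markup Language) is the XML-in-zip interchange
format exported by qPCR instrument software. Only the subset needed for
allele-specific calling is read: samples (id, type), targets (id, dye),
and per-react amplification data points (cycle, fluorescence) plus any
instrument-computed Cq. Everything else in the document is ignored.

The fixture dialect is a long-format CSV (or an equivalent JSON document)
with columns plate, well, sample, sample_type, target, dye, cycle, rfu and
an optional preprocessed_cq — diffable and trivially hand-writable for
tests. ``read_fixture(write_fixture(e))`` preserves all fields.
"""

from __future__ import annotations

import csv
import json
import zipfile
from collections import defaultdict
from pathlib import Path

import numpy as np
from lxml import etree

from .model import (
    Experiment,
    LoadError,
    Plate,
    Reaction,
    SchemaError,
    VersionError,
    Well,
    normalize_position,
)

__all__ = ["read_rdml", "write_rdml", "read_fixture", "write_fixture", "read_any"]

RDML_NS_TEMPLATE = "http://www.rdml.org/rdml/{version}"
SUPPORTED_VERSIONS = ("1.1", "1.2")

FIXTURE_COLUMNS = ("plate", "well", "sample", "sample_type", "target", "dye",
                   "cycle", "rfu")


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _children(elem, name: str):
    return [ch for ch in elem if _local(ch.tag) == name]


def _child(elem, name: str):
    found = _children(elem, name)
    return found[0] if found else None


def _position_from_react_id(react_id: str, rows: int, columns: int) -> str:
    """RDML encodes the well as a linear react id, row-major from A01."""
    try:
        idx = int(react_id) - 1
    except ValueError:
        return normalize_position(react_id)
    if idx < 0 or idx >= rows * columns:
        raise LoadError(f"react id {react_id} outside a {rows}x{columns} plate")
    return f"{chr(ord('A') + idx // columns)}{idx % columns + 1:02d}"


def read_rdml(path) -> Experiment:
    """Read an RDML v1.1 (or structurally identical v1.2) archive.

    One Reaction per react/data element; data points (cyc, fluor) become the
    cycles/rfu arrays; a per-reaction <cq> is kept as preprocessed_cq; RDML
    sample type "ntc" maps to the NTC sample type, everything else to
    unknown.
    """
    path = Path(path)
    try:
        with zipfile.ZipFile(path) as zf:
            xml_names = [n for n in zf.namelist() if n.lower().endswith(".xml")]
            if not xml_names:
                raise LoadError(f"{path.name}: no XML document in archive")
            data = zf.read(xml_names[0])
    except (zipfile.BadZipFile, FileNotFoundError, OSError) as exc:
        raise LoadError(f"cannot read RDML archive {path.name}: {exc}") from exc

    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise LoadError(f"{path.name}: malformed XML: {exc}") from exc

    version = root.get("version", "")
    if version and version.split(".")[0] != "1":
        raise VersionError(f"{path.name}: unsupported RDML version {version}")

    sample_types: dict[str, str] = {}
    for sample in _children(root, "sample"):
        stype = _child(sample, "type")
        text = (stype.text or "").strip().lower() if stype is not None else ""
        sample_types[sample.get("id", "")] = "ntc" if text == "ntc" else "unknown"

    target_dyes: dict[str, str] = {}
    for target in _children(root, "target"):
        dye = _child(target, "dyeId")
        target_dyes[target.get("id", "")] = dye.get("id", "") if dye is not None else ""

    run_date = None
    date_el = _child(root, "dateMade")
    if date_el is not None and date_el.text:
        run_date = date_el.text.strip()

    plates: list[Plate] = []
    n_points = 0
    for experiment in _children(root, "experiment"):
        for run in _children(experiment, "run"):
            rows, columns = 8, 12
            fmt = _child(run, "pcrFormat")
            if fmt is not None:
                r, c = _child(fmt, "rows"), _child(fmt, "columns")
                if r is not None and r.text:
                    rows = int(r.text)
                if c is not None and c.text:
                    columns = int(c.text)
            wells: dict[str, Well] = {}
            for react in _children(run, "react"):
                position = _position_from_react_id(react.get("id", "0"), rows, columns)
                sample_el = _child(react, "sample")
                sample_id = sample_el.get("id", "") if sample_el is not None else ""
                well = wells.get(position)
                if well is None:
                    well = Well(
                        position=position,
                        sample_name=sample_id,
                        sample_type=sample_types.get(sample_id, "unknown"),
                    )
                    wells[position] = well
                for data_el in _children(react, "data"):
                    tar = _child(data_el, "tar")
                    target_id = tar.get("id", "") if tar is not None else ""
                    cq_el = _child(data_el, "cq")
                    cq = None
                    if cq_el is not None and cq_el.text:
                        try:
                            cq = float(cq_el.text)
                        except ValueError:
                            cq = None
                        if cq is not None and not np.isfinite(cq):
                            cq = None
                    cycles, rfu = [], []
                    for adp in _children(data_el, "adp"):
                        cyc_el, fluor_el = _child(adp, "cyc"), _child(adp, "fluor")
                        if cyc_el is None or fluor_el is None:
                            continue
                        cycles.append(float(cyc_el.text))
                        rfu.append(float(fluor_el.text))
                    if not cycles:
                        continue
                    n_points += len(cycles)
                    well.reactions.append(
                        Reaction(
                            target_name=target_id,
                            dye=target_dyes.get(target_id, ""),
                            cycles=np.asarray(cycles),
                            rfu=np.asarray(rfu),
                            preprocessed_cq=cq,
                        )
                    )
            plate_id = run.get("id", "") or experiment.get("id", "") or path.stem
            plate_wells = [wells[p] for p in sorted(wells)]
            if plate_wells:
                plates.append(Plate(plate_id=plate_id, wells=plate_wells))

    if n_points == 0:
        raise LoadError(f"{path.name}: no amplification data")
    return Experiment(file_id=path.stem, plates=plates, run_date=run_date)


def write_rdml(experiment: Experiment, path) -> None:
    """Write an Experiment as a minimal RDML v1.1 archive.

    Output is deterministic (fixed zip timestamp, stable element order) so
    identical experiments produce byte-identical files.
    """
    ns = RDML_NS_TEMPLATE.format(version="1.1")
    root = etree.Element(f"{{{ns}}}rdml", version="1.1", nsmap={None: ns})
    if experiment.run_date:
        etree.SubElement(root, f"{{{ns}}}dateMade").text = experiment.run_date

    samples: dict[str, str] = {}
    targets: dict[str, str] = {}
    for _plate, well, reaction in experiment.iter_reactions():
        samples.setdefault(well.sample_name, well.sample_type)
        targets.setdefault(reaction.target_name, reaction.dye)
    for name in sorted(samples):
        el = etree.SubElement(root, f"{{{ns}}}sample", id=name)
        etree.SubElement(el, f"{{{ns}}}type").text = (
            "ntc" if samples[name] == "ntc" else "unkn"
        )
    for name in sorted(targets):
        el = etree.SubElement(root, f"{{{ns}}}target", id=name)
        etree.SubElement(el, f"{{{ns}}}type").text = "toi"
        etree.SubElement(el, f"{{{ns}}}dyeId", id=targets[name] or "dye")

    exp_el = etree.SubElement(root, f"{{{ns}}}experiment", id=experiment.file_id)
    for plate in experiment.plates:
        run_el = etree.SubElement(exp_el, f"{{{ns}}}run", id=plate.plate_id)
        fmt = etree.SubElement(run_el, f"{{{ns}}}pcrFormat")
        etree.SubElement(fmt, f"{{{ns}}}rows").text = "8"
        etree.SubElement(fmt, f"{{{ns}}}columns").text = "12"
        etree.SubElement(fmt, f"{{{ns}}}rowLabel").text = "ABC"
        etree.SubElement(fmt, f"{{{ns}}}columnLabel").text = "123"
        for well in sorted(plate.wells, key=lambda w: w.position):
            row = ord(well.position[0]) - ord("A")
            col = int(well.position[1:])
            react_id = row * 12 + col
            react = etree.SubElement(run_el, f"{{{ns}}}react", id=str(react_id))
            etree.SubElement(react, f"{{{ns}}}sample", id=well.sample_name)
            for reaction in well.reactions:
                data = etree.SubElement(react, f"{{{ns}}}data")
                etree.SubElement(data, f"{{{ns}}}tar", id=reaction.target_name)
                if reaction.preprocessed_cq is not None:
                    etree.SubElement(data, f"{{{ns}}}cq").text = (
                        f"{reaction.preprocessed_cq:.6f}"
                    )
                for cyc, fluor in zip(reaction.cycles, reaction.rfu):
                    adp = etree.SubElement(data, f"{{{ns}}}adp")
                    etree.SubElement(adp, f"{{{ns}}}cyc").text = f"{cyc:g}"
                    etree.SubElement(adp, f"{{{ns}}}fluor").text = f"{fluor:.6f}"

    xml = etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                         pretty_print=False)
    info = zipfile.ZipInfo("rdml_data.xml", date_time=(1980, 1, 1, 0, 0, 0))
    info.compress_type = zipfile.ZIP_DEFLATED
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr(info, xml)


def write_fixture(experiment: Experiment, path) -> None:
    """Write the long-format CSV (or JSON, by extension) fixture dialect."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        _write_fixture_json(experiment, path)
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(FIXTURE_COLUMNS + ("preprocessed_cq",))
        for plate, well, reaction in experiment.iter_reactions():
            cq = "" if reaction.preprocessed_cq is None else f"{reaction.preprocessed_cq:.6f}"
            for cyc, fluor in zip(reaction.cycles, reaction.rfu):
                writer.writerow([
                    plate.plate_id, well.position, well.sample_name,
                    well.sample_type, reaction.target_name, reaction.dye,
                    f"{cyc:g}", f"{fluor:.6f}", cq,
                ])


def _write_fixture_json(experiment: Experiment, path: Path) -> None:
    doc = {"file_id": experiment.file_id, "run_date": experiment.run_date,
           "plates": []}
    for plate in experiment.plates:
        pl = {"plate_id": plate.plate_id, "wells": []}
        for well in plate.wells:
            w = {"position": well.position, "sample": well.sample_name,
                 "sample_type": well.sample_type, "reactions": []}
            for r in well.reactions:
                w["reactions"].append({
                    "target": r.target_name,
                    "dye": r.dye,
                    "cycles": [float(c) for c in r.cycles],
                    "rfu": [round(float(v), 6) for v in r.rfu],
                    "preprocessed_cq": r.preprocessed_cq,
                })
            pl["wells"].append(w)
        doc["plates"].append(pl)
    path.write_text(json.dumps(doc, indent=1))


def read_fixture(path) -> Experiment:
    """Read the CSV or JSON fixture dialect into an Experiment."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _read_fixture_json(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path.name}: empty fixture")
        missing = [c for c in FIXTURE_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(
                f"{path.name}: fixture missing required column(s) {', '.join(missing)}"
            )
        rows = list(reader)
    plates: dict[str, dict[str, Well]] = defaultdict(dict)
    curves: dict[tuple, dict] = {}
    for row in rows:
        plate_id = row["plate"]
        position = normalize_position(row["well"])
        wells = plates[plate_id]
        if position not in wells:
            wells[position] = Well(
                position=position,
                sample_name=row["sample"],
                sample_type="ntc" if row["sample_type"].lower() == "ntc" else "unknown",
            )
        key = (plate_id, position, row["target"])
        if key not in curves:
            cq_text = (row.get("preprocessed_cq") or "").strip()
            curves[key] = {
                "dye": row["dye"],
                "cq": float(cq_text) if cq_text else None,
                "cycles": [],
                "rfu": [],
            }
        curves[key]["cycles"].append(float(row["cycle"]))
        curves[key]["rfu"].append(float(row["rfu"]))
    for (plate_id, position, target), cv in curves.items():
        plates[plate_id][position].reactions.append(
            Reaction(target_name=target, dye=cv["dye"],
                     cycles=np.asarray(cv["cycles"]), rfu=np.asarray(cv["rfu"]),
                     preprocessed_cq=cv["cq"])
        )
    plate_list = [
        Plate(plate_id=pid, wells=[wells[p] for p in sorted(wells)])
        for pid, wells in plates.items()
    ]
    if not any(w.reactions for pl in plate_list for w in pl.wells):
        raise SchemaError(f"{path.name}: fixture holds no reactions")
    return Experiment(file_id=path.stem, plates=plate_list)


def _read_fixture_json(path: Path) -> Experiment:
    doc = json.loads(path.read_text())
    for field in ("file_id", "plates"):
        if field not in doc:
            raise SchemaError(f"{path.name}: fixture missing field {field!r}")
    plates = []
    for pl in doc["plates"]:
        wells = []
        for w in pl["wells"]:
            reactions = [
                Reaction(target_name=r["target"], dye=r.get("dye", ""),
                         cycles=np.asarray(r["cycles"], dtype=float),
                         rfu=np.asarray(r["rfu"], dtype=float),
                         preprocessed_cq=r.get("preprocessed_cq"))
                for r in w["reactions"]
            ]
            wells.append(Well(position=normalize_position(w["position"]),
                              sample_name=w["sample"],
                              sample_type=w.get("sample_type", "unknown"),
                              reactions=reactions))
        plates.append(Plate(plate_id=pl["plate_id"], wells=wells))
    return Experiment(file_id=doc["file_id"], plates=plates,
                      run_date=doc.get("run_date"))


def read_any(path) -> Experiment:
    """Dispatch on extension: .rdml/.zip -> RDML, .csv/.json -> fixture."""
    suffix = Path(path).suffix.lower()
    if suffix in (".rdml", ".zip"):
        return read_rdml(path)
    if suffix in (".csv", ".json"):
        return read_fixture(path)
    raise LoadError(f"unrecognized input format: {path}")
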