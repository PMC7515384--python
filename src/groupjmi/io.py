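"""File I/O: delimited text and the Mulan multi-label ARFF dialect.

CSV/TSV datasets must carry a header row; target columns are declared
either by name or by a trailing count. Mulan-style multi-label data come as
a dense ARFF file plus a companion XML file listing the label attributes;
nominal {0,1} label attributes are parsed as binary labels.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DataFormatError",
    "read_csv_dataset",
    "write_csv_dataset",
    "read_mulan_arff",
    "write_mulan_arff",
]


class DataFormatError(ValueError):
    """Raised when an input file does not match its declared format."""


def read_csv_dataset(path, target_columns=None, targets_last: int | None = None,
                     sep: str = ","):
    """Read a delimited dataset and split it into features and targets.

    Exactly one of ``target_columns`` (list of column names) or
    ``targets_last`` (the last M columns are targets) must be given.
    Returns ``(X_df, Y_df)``.
    """
    if (target_columns is None) == (targets_last is None):
        raise ValueError("give exactly one of target_columns or targets_last")
    df = pd.read_csv(path, sep=sep)
    if targets_last is not None:
        if not (1 <= targets_last < df.shape[1]):
            raise DataFormatError(
                f"{path}: targets_last={targets_last} out of range for "
                f"{df.shape[1]} columns")
        tcols = list(df.columns[-targets_last:])
    else:
        tcols = list(target_columns)
        missing = [c for c in tcols if c not in df.columns]
        if missing:
            raise DataFormatError(f"{path}: target columns not found: {missing}")
    X = df.drop(columns=tcols)
    Y = df[tcols]
    return X, Y


def write_csv_dataset(path, X, Y, feature_names=None, target_names=None,
                      sep: str = ","):
    """Write features and targets to one delimited file with a header row."""
    X = np.asarray(X)
    Y = np.asarray(Y)
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    if target_names is None:
        target_names = [f"y{t}" for t in range(Y.shape[1])]
    df = pd.DataFrame(X, columns=list(feature_names))
    for t, name in enumerate(target_names):
        df[name] = Y[:, t]
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Mulan ARFF dialect
# ---------------------------------------------------------------------------


def _parse_attribute(line: str, path) -> tuple[str, str]:
    body = line[len("@attribute"):].strip()
    if body.startswith("'"):
        end = body.index("'", 1)
        name, rest = body[1:end], body[end + 1:].strip()
    else:
        parts = body.split(None, 1)
        if len(parts) != 2:
            raise DataFormatError(f"{path}: malformed @attribute line: {line!r}")
        name, rest = parts
    return name, rest.strip()


def read_mulan_arff(arff_path, xml_path):
    """Read a dense Mulan multi-label ARFF file plus its label-list XML.

    Returns ``(X_df, Y_df)`` where Y holds the label columns named in the
    XML (nominal {0,1} attributes), in XML order, coded as integers.
    """
    arff_path, xml_path = Path(arff_path), Path(xml_path)
    labels = _read_label_xml(xml_path)

    names: list[str] = []
    kinds: list[str] = []
    data_lines: list[str] = []
    in_data = False
    for raw in arff_path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        low = line.lower()
        if in_data:
            if line.startswith("{"):
                raise DataFormatError(
                    f"{arff_path}: sparse ARFF data is not supported")
            data_lines.append(line)
        elif low.startswith("@attribute"):
            name, kind = _parse_attribute(line, arff_path)
            names.append(name)
            kinds.append(kind)
        elif low.startswith("@data"):
            in_data = True
        elif low.startswith("@relation"):
            continue
        else:
            raise DataFormatError(f"{arff_path}: unexpected line {line!r}")
    if not in_data:
        raise DataFormatError(f"{arff_path}: missing @data section")
    missing = [l for l in labels if l not in names]
    if missing:
        raise DataFormatError(
            f"{xml_path}: labels not present in {arff_path.name}: {missing}")

    rows = [line.split(",") for line in data_lines]
    widths = {len(r) for r in rows}
    if widths and widths != {len(names)}:
        raise DataFormatError(
            f"{arff_path}: data rows with {widths} fields, expected {len(names)}")
    df = pd.DataFrame(rows, columns=names)
    label_set = set(labels)
    for name, kind in zip(names, kinds):
        if kind.startswith("{"):
            df[name] = df[name].str.strip().astype(np.int64)
        elif kind.lower() in ("numeric", "real", "integer"):
            df[name] = df[name].astype(float)
        else:
            raise DataFormatError(
                f"{arff_path}: unsupported attribute type {kind!r} for "
                f"field {name!r}")
        if name in label_set and not df[name].isin([0, 1]).all():
            raise DataFormatError(
                f"{arff_path}: label {name!r} has values outside {{0,1}}")
    Y = df[labels].astype(np.int64)
    X = df.drop(columns=labels)
    return X, Y


def _read_label_xml(xml_path: Path) -> list[str]:
    try:
        root = ET.parse(xml_path).getroot()
    except ET.ParseError as exc:
        raise DataFormatError(f"{xml_path}: malformed XML ({exc})") from exc
    labels = [el.attrib["name"] for el in root.iter()
              if el.tag.split("}")[-1] == "label" and "name" in el.attrib]
    if not labels:
        raise DataFormatError(f"{xml_path}: no <label name=...> entries found")
    return labels


def write_mulan_arff(arff_path, xml_path, X, Y, feature_names=None,
                     target_names=None, relation: str = "synthetic"):
    """Write a dense Mulan-style ARFF file and its companion label XML."""
    X = np.asarray(X)
    Y = np.asarray(Y).astype(np.int64)
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    if target_names is None:
        target_names = [f"y{t}" for t in range(Y.shape[1])]
    lines = [f"@relation {relation}", ""]
    for name in feature_names:
        lines.append(f"@attribute {name} numeric")
    for name in target_names:
        lines.append(f"@attribute {name} {{0,1}}")
    lines.append("")
    lines.append("@data")
    for i in range(X.shape[0]):
        feats = ",".join(repr(float(v)) for v in X[i])
        labs = ",".join(str(int(v)) for v in Y[i])
        lines.append(f"{feats},{labs}" if feats else labs)
    Path(arff_path).write_text("\n".join(lines) + "\n")

    root = ET.Element("labels", xmlns="http://mulan.sourceforge.net/labels")
    for name in target_names:
        ET.SubElement(root, "label", name=name)
    ET.ElementTree(root).write(xml_path, encoding="unicode",
                               xml_declaration=True)
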