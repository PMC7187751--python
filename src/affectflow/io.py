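"""Readers and writers for post, user, and source-corpus tables.

Two dialects are supported and auto-detected by extension: comma-delimited
tables (``.csv``) and record-per-line JSON (``.jsonl`` / ``.ndjson`` /
``.json``). On disk, affect polarities use the ASCII tokens
``pos/neg/mix/neu``; the silence symbol is derived downstream and never
stored.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path
from typing import Optional

import pandas as pd

from .core import (
    AFFECT_TO_TOKEN,
    Post,
    SchemaError,
    UserProfile,
    parse_affect,
)

POST_COLUMNS = ["user_id", "created_at", "text", "affect", "language",
                "originality_gold"]
USER_COLUMNS = ["user_id", "age", "gender", "ethnicity", "living_status",
                "ope", "con", "ext", "agr", "neu", "swl", "cesd", "cesd_date"]
CORPUS_COLUMNS = ["doc_id", "site_name", "url", "text"]

_REQUIRED_POST = ("user_id", "created_at", "affect")


def _detect_dialect(path: Path, dialect: Optional[str]) -> str:
    if dialect is not None:
        if dialect not in ("csv", "jsonl"):
            raise ValueError(f"unknown dialect {dialect!r}")
        return dialect
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in (".jsonl", ".ndjson", ".json"):
        return "jsonl"
    raise ValueError(f"cannot infer dialect from extension {suffix!r}; "
                     "pass dialect='csv' or 'jsonl'")


def _read_frame(path: Path, dialect: Optional[str]) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(path)
    mode = _detect_dialect(path, dialect)
    if path.stat().st_size == 0:
        return pd.DataFrame()
    if mode == "csv":
        try:
            return pd.read_csv(path, dtype=str, keep_default_na=False)
        except pd.errors.EmptyDataError:
            return pd.DataFrame()
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                records.append(json.loads(line))
            except json.JSONDecodeError as exc:
                raise SchemaError(f"{path}: line {lineno} is not valid JSON: "
                                  f"{exc}") from exc
    return pd.DataFrame.from_records(records).astype(str) if records else pd.DataFrame()


def _parse_datetime(value: str, row: int) -> _dt.datetime:
    v = str(value).strip()
    ts = pd.to_datetime(v, errors="coerce", format="ISO8601")
    if pd.isna(ts):
        raise SchemaError(f"row {row}: unparseable date {value!r}")
    return ts.to_pydatetime()


def read_posts(path, dialect: Optional[str] = None) -> list[Post]:
    """Read a posts table into :class:`Post` records.

    Required fields: ``user_id``, ``created_at`` (ISO-8601), ``affect``
    (``pos/neg/mix/neu``). Optional: ``text``, ``language``,
    ``originality_gold``, ``post_id``. An empty file yields an empty list.
    Rows with invalid affect symbols or unparseable dates are reported with
    their (1-based, header-excluded) row numbers.
    """
    frame = _read_frame(Path(path), dialect)
    if frame.empty:
        return []
    missing = [c for c in _REQUIRED_POST if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required field(s) "
                          f"{', '.join(missing)}")
    posts: list[Post] = []
    problems: list[str] = []
    for i, rec in enumerate(frame.to_dict("records"), start=1):
        try:
            gold = rec.get("originality_gold") or None
            if gold in ("", "None", "nan"):
                gold = None
            posts.append(Post(
                user_id=str(rec["user_id"]),
                created_at=_parse_datetime(rec["created_at"], i),
                affect=parse_affect(rec["affect"]),
                text=str(rec.get("text", "") or ""),
                language=str(rec.get("language") or "en"),
                originality_gold=gold,
                post_id=(str(rec["post_id"]) if rec.get("post_id") else None),
            ))
        except SchemaError as exc:
            problems.append(f"row {i}: {exc}" if "row" not in str(exc) else str(exc))
    if problems:
        raise SchemaError(f"{path}: {len(problems)} invalid row(s): "
                          + "; ".join(problems[:10]))
    return posts


def write_posts(posts: list[Post], path, dialect: Optional[str] = None) -> None:
    path = Path(path)
    mode = _detect_dialect(path, dialect)
    records = []
    for p in posts:
        records.append({
            "user_id": p.user_id,
            "created_at": p.created_at.isoformat(),
            "text": p.text,
            "affect": AFFECT_TO_TOKEN[p.affect],
            "language": p.language,
            "originality_gold": p.originality_gold or "",
            "post_id": p.post_id or "",
        })
    _write_records(records, path, mode,
                   columns=POST_COLUMNS + ["post_id"])


def read_users(path, dialect: Optional[str] = None) -> list[UserProfile]:
    """Read a users table; scale ranges are validated row by row and
    duplicate user ids rejected."""
    frame = _read_frame(Path(path), dialect)
    if frame.empty:
        return []
    missing = [c for c in USER_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required field(s) "
                          f"{', '.join(missing)}")
    users: list[UserProfile] = []
    seen: set[str] = set()
    problems: list[str] = []
    for i, rec in enumerate(frame.to_dict("records"), start=1):
        uid = str(rec["user_id"])
        if uid in seen:
            problems.append(f"row {i}: duplicate user_id {uid!r}")
            continue
        seen.add(uid)
        try:
            users.append(UserProfile(
                user_id=uid,
                age=float(rec["age"]),
                gender=str(rec.get("gender") or "unknown"),
                ethnicity=str(rec.get("ethnicity") or "unknown"),
                living_status=str(rec.get("living_status") or "unknown"),
                ope=float(rec["ope"]), con=float(rec["con"]),
                ext=float(rec["ext"]), agr=float(rec["agr"]),
                neu=float(rec["neu"]), swl=float(rec["swl"]),
                cesd=int(float(rec["cesd"])),
                cesd_date=_parse_datetime(rec["cesd_date"], i).date(),
            ))
        except (SchemaError, ValueError) as exc:
            problems.append(f"row {i}: {exc}")
    if problems:
        raise SchemaError(f"{path}: {len(problems)} invalid row(s): "
                          + "; ".join(problems[:10]))
    return users


def write_users(users: list[UserProfile], path,
                dialect: Optional[str] = None) -> None:
    path = Path(path)
    mode = _detect_dialect(path, dialect)
    records = []
    for u in users:
        rec = {c: getattr(u, c) for c in USER_COLUMNS}
        rec["cesd_date"] = u.cesd_date.isoformat()
        records.append(rec)
    _write_records(records, path, mode, columns=USER_COLUMNS)


def read_corpus(path, dialect: Optional[str] = None):
    """Read a candidate-source corpus (doc_id, site_name, url, text)."""
    from .originality import SourceDoc

    frame = _read_frame(Path(path), dialect)
    if frame.empty:
        return []
    missing = [c for c in ("doc_id", "text") if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required field(s) "
                          f"{', '.join(missing)}")
    docs = []
    for i, rec in enumerate(frame.to_dict("records"), start=1):
        text = str(rec.get("text", ""))
        if not text:
            raise SchemaError(f"{path}: row {i}: empty document text")
        docs.append(SourceDoc(
            doc_id=str(rec["doc_id"]),
            text=text,
            site_name=str(rec.get("site_name") or ""),
            url=str(rec.get("url") or ""),
        ))
    return docs


def write_corpus(docs, path, dialect: Optional[str] = None) -> None:
    path = Path(path)
    mode = _detect_dialect(path, dialect)
    records = [{"doc_id": d.doc_id, "site_name": d.site_name,
                "url": d.url, "text": d.text} for d in docs]
    _write_records(records, path, mode, columns=CORPUS_COLUMNS)


def _write_records(records: list[dict], path: Path, mode: str,
                   columns: list[str]) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    if mode == "csv":
        frame = pd.DataFrame.from_records(records, columns=columns)
        frame.to_csv(path, index=False)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            for rec in records:
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
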