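"""Turn a fitted classification tree into an administerable questionnaire.

Every internal node becomes one binary question ("Do you consume >=
{threshold} servings/day of {food}?"); answering yes follows the tree's
right (">=") branch, no the left. Each root-to-leaf pathway ends in a
verdict, "low" or "high" diet quality. Administering the questionnaire to
a respondent reproduces the source tree's prediction exactly: question
text rounds thresholds for display, but routing always compares against
the unrounded values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .cart import CLASSES, Tree, TreeNode, tree_to_dict
from .ffq import ItemCatalog

QUESTIONNAIRE_SCHEMA_VERSION = 1

VERDICTS = CLASSES


class QuestionnaireError(ValueError):
    """Raised for malformed questionnaires or unanswerable pathways."""


@dataclass(frozen=True)
class Question:
    """One binary question. Branches are ``("question", qid)`` or
    ``("verdict", "low"/"high")``."""

    question_id: str
    predictor_id: str
    text: str
    threshold: float
    yes_branch: tuple[str, str]
    no_branch: tuple[str, str]


@dataclass(frozen=True)
class Pathway:
    question_ids: tuple[str, ...]
    answers: tuple[str, ...]  # "yes"/"no", aligned with question_ids
    verdict: str


@dataclass(frozen=True)
class Questionnaire:
    questions: Mapping[str, Question]
    entry_question_id: str | None  # None for a trivial single-verdict tool
    pathways: tuple[Pathway, ...]
    metadata: Mapping[str, object] = field(default_factory=dict)
    default_verdict: str | None = None  # used when entry_question_id is None

    @property
    def max_pathway_length(self) -> int:
        return max((len(p.question_ids) for p in self.pathways), default=0)


@dataclass(frozen=True)
class AdministerResult:
    verdict: str
    pathway: tuple[str, ...]
    n_questions_asked: int


def _question_text(predictor_id: str, threshold: float, catalog: ItemCatalog) -> str:
    if predictor_id == "sex":
        return "Are you male?"
    if predictor_id == "age":
        return f"Are you {threshold:.0f} years of age or older?"
    if predictor_id in catalog.groups:
        label = catalog.group_label(predictor_id)
    else:
        label = catalog.item(predictor_id).label  # KeyError if unknown
    return (
        f"Do you consume {threshold:.2f} or more servings per day of {label}?"
    )


def tree_to_questionnaire(tree: Tree, catalog: ItemCatalog) -> Questionnaire:
    """Convert a fitted tree into a questionnaire.

    Raises :class:`QuestionnaireError` if a tree predictor is neither a
    catalog item/group nor a demographic (age, sex).
    """
    for pid in sorted(tree.split_features()):
        if pid in ("age", "sex") or pid in catalog.groups:
            continue
        try:
            catalog.item(pid)
        except KeyError:
            raise QuestionnaireError(
                f"tree predictor {pid!r} is not in the catalog"
            ) from None

    questions: dict[str, Question] = {}
    counter = 0

    def _build(node: TreeNode):
        nonlocal counter
        if node.is_leaf:
            return ("verdict", node.prediction)
        counter += 1
        qid = f"Q{counter}"
        pid = tree.predictor_ids[node.feature]
        no_branch = _build(node.left)  # value < threshold -> "no"
        yes_branch = _build(node.right)
        questions[qid] = Question(
            question_id=qid,
            predictor_id=pid,
            text=_question_text(pid, node.threshold, catalog),
            threshold=float(node.threshold),
            yes_branch=yes_branch,
            no_branch=no_branch,
        )
        return ("question", qid)

    entry = _build(tree.root)
    tree_hash = hashlib.sha256(
        json.dumps(tree_to_dict(tree), sort_keys=True).encode()
    ).hexdigest()
    metadata = {
        "source_tree_sha256": tree_hash,
        "threshold_units": "servings/day",
        "seed": tree.seed,
    }
    if entry[0] == "verdict":
        return Questionnaire(
            questions={},
            entry_question_id=None,
            pathways=(Pathway((), (), entry[1]),),
            metadata=metadata,
            default_verdict=entry[1],
        )
    q = Questionnaire(
        questions=questions,
        entry_question_id=entry[1],
        pathways=(),
        metadata=metadata,
    )
    return Questionnaire(
        questions=questions,
        entry_question_id=entry[1],
        pathways=tuple(_enumerate_pathways(q)),
        metadata=metadata,
    )


def _enumerate_pathways(q: Questionnaire) -> list[Pathway]:
    out: list[Pathway] = []

    def _walk(branch, qids, answers):
        kind, target = branch
        if kind == "verdict":
            out.append(Pathway(tuple(qids), tuple(answers), target))
            return
        question = q.questions[target]
        _walk(question.no_branch, qids + [target], answers + ["no"])
        _walk(question.yes_branch, qids + [target], answers + ["yes"])

    if q.entry_question_id is None:
        return [Pathway((), (), q.default_verdict)]
    _walk(("question", q.entry_question_id), [], [])
    return out


def _predictor_value(
    question: Question, respondent_row: Mapping, catalog: ItemCatalog
) -> float:
    pid = question.predictor_id
    if pid == "sex":
        return 1.0 if respondent_row["sex"] == "male" else 0.0
    if pid == "age":
        return float(respondent_row["age"])
    if pid in catalog.groups:
        return float(
            sum(float(respondent_row.get(m, 0.0)) for m in catalog.groups[pid])
        )
    return float(respondent_row.get(pid, 0.0))


def administer(
    q: Questionnaire,
    answers: Mapping[str, str] | None = None,
    respondent: Mapping | None = None,
    catalog: ItemCatalog | None = None,
) -> AdministerResult:
    """Walk the questionnaire and return the verdict.

    Either explicit yes/no ``answers`` (keyed by question id; only the
    questions on the taken pathway are required, others are ignored) or a
    ``respondent`` row plus ``catalog`` (answers derived from intakes).
    """
    if answers is None and respondent is None:
        raise QuestionnaireError("provide either answers or a respondent")
    if respondent is not None and catalog is None:
        raise QuestionnaireError("intakes mode requires a catalog")
    if q.entry_question_id is None:
        return AdministerResult(q.default_verdict, (), 0)
    asked: list[str] = []
    branch = ("question", q.entry_question_id)
    while branch[0] == "question":
        question = q.questions[branch[1]]
        asked.append(question.question_id)
        if answers is not None:
            if question.question_id not in answers:
                raise QuestionnaireError(
                    f"missing answer for question {question.question_id} "
                    f"({question.text!r})"
                )
            ans = str(answers[question.question_id]).lower()
            if ans not in ("yes", "no"):
                raise QuestionnaireError(
                    f"answer for {question.question_id} must be yes/no, got {ans!r}"
                )
            yes = ans == "yes"
        else:
            yes = _predictor_value(question, respondent, catalog) >= question.threshold
        branch = question.yes_branch if yes else question.no_branch
    return AdministerResult(branch[1], tuple(asked), len(asked))


def administer_cohort(
    q: Questionnaire, cohort: pd.DataFrame, catalog: ItemCatalog
) -> pd.DataFrame:
    """Batch intakes-mode administration; one verdict row per respondent."""
    records = []
    for _, row in cohort.iterrows():
        res = administer(q, respondent=row, catalog=catalog)
        records.append(
            {
                "respondent_id": row["respondent_id"],
                "verdict": res.verdict,
                "n_questions_asked": res.n_questions_asked,
            }
        )
    return pd.DataFrame(records, index=cohort.index)


# ---------------------------------------------------------------------------
# Serialization


def serialize(q: Questionnaire) -> str:
    """Stable JSON text (sorted keys) for diff-able artifacts."""
    data = {
        "schema_version": QUESTIONNAIRE_SCHEMA_VERSION,
        "entry_question_id": q.entry_question_id,
        "default_verdict": q.default_verdict,
        "metadata": dict(q.metadata),
        "questions": {
            qid: {
                "predictor_id": question.predictor_id,
                "text": question.text,
                "threshold": question.threshold,
                "yes_branch": list(question.yes_branch),
                "no_branch": list(question.no_branch),
            }
            for qid, question in q.questions.items()
        },
        "pathways": [
            {
                "question_ids": list(p.question_ids),
                "answers": list(p.answers),
                "verdict": p.verdict,
            }
            for p in q.pathways
        ],
    }
    return json.dumps(data, indent=2, sort_keys=True)


def deserialize(text: str | bytes) -> Questionnaire:
    """Parse and validate serialized questionnaire JSON."""
    data = json.loads(text)
    if data.get("schema_version") != QUESTIONNAIRE_SCHEMA_VERSION:
        raise QuestionnaireError(
            f"unsupported questionnaire schema_version "
            f"{data.get('schema_version')!r}"
        )
    questions: dict[str, Question] = {}
    for qid, raw in data.get("questions", {}).items():
        questions[qid] = Question(
            question_id=qid,
            predictor_id=raw["predictor_id"],
            text=raw["text"],
            threshold=float(raw["threshold"]),
            yes_branch=tuple(raw["yes_branch"]),
            no_branch=tuple(raw["no_branch"]),
        )
    for qid, question in questions.items():
        for branch in (question.yes_branch, question.no_branch):
            kind, target = branch
            if kind == "question":
                if target not in questions:
                    raise QuestionnaireError(
                        f"question {qid} references unknown question {target!r}"
                    )
            elif kind == "verdict":
                if target not in VERDICTS:
                    raise QuestionnaireError(
                        f"question {qid} has invalid verdict {target!r}"
                    )
            else:
                raise QuestionnaireError(
                    f"question {qid} has invalid branch kind {kind!r}"
                )
    entry = data.get("entry_question_id")
    if entry is not None and entry not in questions:
        raise QuestionnaireError(f"entry question {entry!r} does not exist")
    # reject cycles / reconvergence: each question reachable along one path
    if entry is not None:
        seen: set[str] = set()
        stack = [entry]
        while stack:
            qid = stack.pop()
            if qid in seen:
                raise QuestionnaireError(
                    f"question {qid!r} is reachable along more than one path"
                )
            seen.add(qid)
            for branch in (questions[qid].no_branch, questions[qid].yes_branch):
                if branch[0] == "question":
                    stack.append(branch[1])
    pathways = tuple(
        Pathway(tuple(p["question_ids"]), tuple(p["answers"]), p["verdict"])
        for p in data.get("pathways", [])
    )
    return Questionnaire(
        questions=questions,
        entry_question_id=entry,
        pathways=pathways,
        metadata=dict(data.get("metadata", {})),
        default_verdict=data.get("default_verdict"),
    )


def save_questionnaire(q: Questionnaire, path: str | Path) -> None:
    Path(path).write_text(serialize(q))


def load_questionnaire(path: str | Path) -> Questionnaire:
    return deserialize(Path(path).read_text())
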