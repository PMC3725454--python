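"""Symbolic covariance-structure model specifications.

A model is written in a small lavaan-like text grammar:

``Factor =~ ind1 + 1*ind2 + ind3``
    measurement loadings; a ``value*name`` term fixes the loading.
``Target ~ Source1 + Source2``
    structural regressions among latent factors.
``A ~~ B``
    factor covariance (or variance when ``A == B``); ``value*B`` fixes it.

Residual variances of observed indicators are added automatically (free).
A latent factor's variance defaults to fixed 1 when all its loadings are
free (standardized exogenous factor) and to a free (disturbance) variance
when one loading is fixed as a marker.  Explicit ``F ~~ F`` statements
override the default.

Internally the model maps onto the RAM convention: an asymmetric path
matrix ``A`` (loadings and regressions), a symmetric covariance matrix
``S`` (variances, disturbances, covariances) and the selection matrix
``F`` picking out observed rows, so that the implied covariance is
``F (I-A)^-1 S (I-A)^-T F^T``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .exceptions import IdentificationError, ModelSyntaxError, SpecificationError

__all__ = [
    "ModelSpec",
    "parse_model_syntax",
    "parse_model_yaml",
    "serialize_model",
    "count_free_parameters",
    "degrees_of_freedom",
    "check_identification",
]


@dataclass(frozen=True)
class Loading:
    factor: str
    indicator: str
    fixed: Optional[float] = None  # None = free

    @property
    def pid(self) -> str:
        return f"{self.factor}=~{self.indicator}"


@dataclass(frozen=True)
class Path:
    source: str
    target: str
    fixed: Optional[float] = None

    @property
    def pid(self) -> str:
        return f"{self.target}~{self.source}"


@dataclass(frozen=True)
class Covariance:
    """Variance (var1 == var2) or covariance entry of the symmetric matrix."""

    var1: str
    var2: str
    fixed: Optional[float] = None

    @property
    def pid(self) -> str:
        a, b = sorted((self.var1, self.var2))
        return f"{a}~~{b}"


@dataclass
class ModelSpec:
    """Parsed covariance-structure model.

    ``latent_vars`` maps factor name -> endogenous flag (True when the
    factor is the target of at least one structural path).
    ``constraints`` lists equality classes: groups of parameter ids that
    share a single free parameter.
    """

    observed_vars: list[str]
    latent_vars: dict[str, bool]
    loadings: list[Loading]
    structural_paths: list[Path]
    factor_covariances: list[Covariance]
    residual_variances: list[Covariance]
    constraints: list[list[str]] = field(default_factory=list)

    # -- parameter bookkeeping -------------------------------------------

    def all_entries(self):
        return (
            list(self.loadings)
            + list(self.structural_paths)
            + list(self.factor_covariances)
            + list(self.residual_variances)
        )

    def free_entries(self):
        return [e for e in self.all_entries() if e.fixed is None]

    def free_parameter_ids(self) -> list[str]:
        """Ordered distinct free-parameter ids after equality merging.

        Each equality class is represented by its first member; the map
        from parameter entries to indices is checked to be a bijection.
        """
        rep = {}
        for cls in self.constraints:
            for pid in cls:
                rep[pid] = cls[0]
        seen: dict[str, None] = {}
        for e in self.free_entries():
            seen.setdefault(rep.get(e.pid, e.pid), None)
        return list(seen)

    def validate(self) -> None:
        names = set(self.observed_vars) | set(self.latent_vars)
        if len(self.observed_vars) != len(set(self.observed_vars)):
            raise SpecificationError("duplicate observed variable names")
        if set(self.observed_vars) & set(self.latent_vars):
            raise SpecificationError(
                "a name cannot be both observed and latent: "
                f"{sorted(set(self.observed_vars) & set(self.latent_vars))}"
            )
        for ld in self.loadings:
            if ld.factor not in self.latent_vars:
                raise SpecificationError(f"loading on undeclared factor {ld.factor!r}")
            if ld.indicator not in self.observed_vars:
                raise SpecificationError(
                    f"indicator {ld.indicator!r} not among observed variables"
                )
        for pa in self.structural_paths:
            for end in (pa.source, pa.target):
                if end not in self.latent_vars:
                    raise SpecificationError(
                        f"structural path endpoint {end!r} is not a declared latent"
                    )
        for cv in self.factor_covariances + self.residual_variances:
            for v in (cv.var1, cv.var2):
                if v not in names:
                    raise SpecificationError(f"unknown variable {v!r} in covariance")
        pids = [e.pid for e in self.all_entries()]
        dup = {p for p in pids if pids.count(p) > 1}
        if dup:
            raise SpecificationError(f"duplicate parameter entries: {sorted(dup)}")
        for cls in self.constraints:
            known = set(pids)
            for pid in cls:
                if pid not in known:
                    raise SpecificationError(f"constraint on unknown parameter {pid!r}")


_TERM_RE = re.compile(r"^(?:(?P<val>[-+]?[0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?)\*)?(?P<name>[A-Za-z_][\w.%]*)$")


def _parse_terms(rhs: str, lineno: int):
    out = []
    for raw in rhs.split("+"):
        term = raw.strip()
        if not term:
            raise ModelSyntaxError(f"line {lineno}: empty term in {rhs!r}")
        m = _TERM_RE.match(term)
        if not m:
            raise ModelSyntaxError(f"line {lineno}: cannot parse term {term!r}")
        val = m.group("val")
        out.append((m.group("name"), None if val is None else float(val)))
    return out


def parse_model_syntax(text: str) -> ModelSpec:
    """Parse model-definition text into a validated :class:`ModelSpec`."""
    loadings: list[Loading] = []
    paths: list[Path] = []
    covs: list[Covariance] = []
    latent_order: dict[str, None] = {}
    observed_order: dict[str, None] = {}
    explicit_var: dict[str, Covariance] = {}

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        for op in ("=~", "~~", "~"):
            if op in line:
                lhs, rhs = (s.strip() for s in line.split(op, 1))
                break
        else:
            raise ModelSyntaxError(f"line {lineno}: no operator in {line!r}")
        if not re.match(r"^[A-Za-z_][\w.%]*$", lhs):
            raise ModelSyntaxError(f"line {lineno}: bad left-hand side {lhs!r}")
        terms = _parse_terms(rhs, lineno)
        if op == "=~":
            latent_order.setdefault(lhs, None)
            for name, val in terms:
                loadings.append(Loading(lhs, name, val))
                observed_order.setdefault(name, None)
        elif op == "~":
            latent_order.setdefault(lhs, None)
            for name, val in terms:
                paths.append(Path(source=name, target=lhs, fixed=val))
        else:  # ~~
            for name, val in terms:
                cv = Covariance(lhs, name, val)
                observed_order.setdefault(lhs, None)
                observed_order.setdefault(name, None)
                if lhs == name:
                    if lhs in explicit_var and explicit_var[lhs].fixed != val:
                        raise SpecificationError(
                            f"line {lineno}: contradictory variance statements for {lhs!r}"
                        )
                    explicit_var[lhs] = cv
                else:
                    covs.append(cv)

    latent = dict.fromkeys(latent_order, False)
    for pa in paths:
        # endpoints must be latent; tolerate declaration via "~" only on lhs
        if pa.target in latent:
            latent[pa.target] = True
    observed = [v for v in observed_order if v not in latent]

    # contradictory fixed loadings on the same (factor, indicator) pair
    seen_load: dict[tuple, Optional[float]] = {}
    for ld in loadings:
        key = (ld.factor, ld.indicator)
        if key in seen_load and seen_load[key] != ld.fixed:
            raise SpecificationError(f"contradictory fixed values for {ld.pid}")
        seen_load[key] = ld.fixed

    # default residual variances for observed vars
    resid = []
    for v in observed:
        resid.append(explicit_var.pop(v, Covariance(v, v, None)))

    # latent variances: explicit statement wins; otherwise fixed 1 unless a
    # marker loading sets the scale, in which case the variance is free
    fcovs = list(covs)
    for f in latent:
        if f in explicit_var:
            fcovs.append(explicit_var.pop(f))
        else:
            has_marker = any(ld.factor == f and ld.fixed is not None for ld in loadings)
            fcovs.append(Covariance(f, f, None if has_marker else 1.0))
    for v, cv in explicit_var.items():
        raise SpecificationError(f"variance statement for unknown variable {v!r}")

    spec = ModelSpec(
        observed_vars=observed,
        latent_vars=latent,
        loadings=loadings,
        structural_paths=paths,
        factor_covariances=fcovs,
        residual_variances=resid,
    )
    spec.validate()
    return spec


def parse_model_yaml(text: str) -> ModelSpec:
    """Parse the YAML encoding of a model — an alternative to the text
    grammar with the same semantics::

        factors:
          Severity: ["1*ADS", PACS, COUNT, DRINC, CIWA]
          AlcoholUse: [DPDD, BINGE_PCT]
        regressions:
          Severity: [AlcoholUse]
        covariances:
          - [AlcoholUse, Affective]

    Fixed values use the same ``value*name`` term syntax.
    """
    import yaml

    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as e:
        raise ModelSyntaxError(f"invalid YAML model specification: {e}")
    if not isinstance(doc, dict):
        raise ModelSyntaxError("YAML model specification must be a mapping")
    lines = []
    for factor, inds in (doc.get("factors") or {}).items():
        lines.append(f"{factor} =~ " + " + ".join(str(t) for t in inds))
    for target, sources in (doc.get("regressions") or {}).items():
        lines.append(f"{target} ~ " + " + ".join(str(t) for t in sources))
    for pair in doc.get("covariances") or []:
        if not isinstance(pair, (list, tuple)) or len(pair) != 2:
            raise ModelSyntaxError(f"covariance entry must be a pair, got {pair!r}")
        lines.append(f"{pair[0]} ~~ {pair[1]}")
    for var, val in (doc.get("variances") or {}).items():
        lines.append(f"{var} ~~ {val}*{var}" if not isinstance(val, str) else f"{var} ~~ {val}")
    return parse_model_syntax("\n".join(lines) + "\n")


def serialize_model(spec: ModelSpec) -> str:
    """Emit model text that re-parses to an identical specification."""

    def term(name, fixed):
        return name if fixed is None else f"{fixed:g}*{name}"

    lines = []
    for f in spec.latent_vars:
        inds = [ld for ld in spec.loadings if ld.factor == f]
        if inds:
            lines.append(f"{f} =~ " + " + ".join(term(ld.indicator, ld.fixed) for ld in inds))
    by_target: dict[str, list[Path]] = {}
    for pa in spec.structural_paths:
        by_target.setdefault(pa.target, []).append(pa)
    for tgt, pas in by_target.items():
        lines.append(f"{tgt} ~ " + " + ".join(term(p.source, p.fixed) for p in pas))
    for cv in spec.factor_covariances:
        if cv.var1 != cv.var2:
            lines.append(f"{cv.var1} ~~ {term(cv.var2, cv.fixed)}")
    # variances only when they deviate from the parse defaults
    default = {}
    for f in spec.latent_vars:
        has_marker = any(ld.factor == f and ld.fixed is not None for ld in spec.loadings)
        default[f] = None if has_marker else 1.0
    for cv in spec.factor_covariances:
        if cv.var1 == cv.var2 and cv.fixed != default.get(cv.var1, "missing"):
            lines.append(f"{cv.var1} ~~ {term(cv.var1, cv.fixed)}")
    for cv in spec.residual_variances:
        if cv.fixed is not None:
            lines.append(f"{cv.var1} ~~ {term(cv.var1, cv.fixed)}")
    return "\n".join(lines) + "\n"


def count_free_parameters(spec: ModelSpec) -> int:
    """Number of distinct free parameters after equality constraints."""
    spec.validate()
    return len(spec.free_parameter_ids())


def degrees_of_freedom(spec: ModelSpec, p: Optional[int] = None) -> int:
    """Model degrees of freedom: p(p+1)/2 - free parameter count."""
    spec.validate()
    if p is None:
        p = len(spec.observed_vars)
    if p != len(spec.observed_vars):
        raise SpecificationError(
            f"p={p} does not match the spec's {len(spec.observed_vars)} observed variables"
        )
    df = p * (p + 1) // 2 - count_free_parameters(spec)
    if df < 0:
        raise IdentificationError(
            f"over-parameterized model: {count_free_parameters(spec)} free parameters "
            f"exceed {p * (p + 1) // 2} sample moments"
        )
    return df


def check_identification(spec: ModelSpec, strict: bool = True) -> list[str]:
    """Run identification checks; return warnings, raise on hard violations.

    Hard violations: a latent factor whose scale is set both by a fixed
    marker loading and a fixed variance, or by neither; negative degrees of
    freedom.  Soft warnings (returned, raised only when ``strict``):
    counting-rule under-identification such as single-indicator factors.
    """
    spec.validate()
    warnings: list[str] = []
    for f in spec.latent_vars:
        fixed_loadings = [ld for ld in spec.loadings if ld.factor == f and ld.fixed is not None]
        var_entry = next(
            cv for cv in spec.factor_covariances if cv.var1 == f and cv.var2 == f
        )
        var_fixed = var_entry.fixed is not None
        if fixed_loadings and var_fixed:
            raise IdentificationError(
                f"factor {f!r} has both a fixed marker loading and a fixed variance"
            )
        if not fixed_loadings and not var_fixed and not any(
            pa.target == f for pa in spec.structural_paths
        ):
            raise IdentificationError(
                f"factor {f!r} has no scale: fix one loading or its variance"
            )
        n_ind = sum(1 for ld in spec.loadings if ld.factor == f)
        if 0 < n_ind < 3 and len(spec.latent_vars) == 1:
            warnings.append(
                f"factor {f!r} has only {n_ind} indicator(s); "
                "under-identified without further constraints"
            )
    try:
        df = degrees_of_freedom(spec)
    except IdentificationError:
        raise
    if df == 0:
        warnings.append("just-identified model (df = 0)")
    if strict and warnings and any("under-identified" in w for w in warnings):
        raise IdentificationError("; ".join(warnings))
    return warnings
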