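"""Bridge to lme4/lmerTest (via Rscript) for crossed random-effects models.

Crossed participant × item random effects with slopes are the standard
analysis for this design, and lme4 is the reference implementation for
fitting them by REML; lmerTest supplies Satterthwaite degrees of freedom.
The simplification ladder runs inside a single R process per fit: start
with the full (correlated) random-effect structure, drop the correlations,
then drop random slopes one at a time — interaction slopes first, then the
slope with the smallest estimated variance — until a model converges
without being singular.  If the ladder bottoms out, the last converged
(possibly singular) fit is accepted and flagged.

Everything crosses the process boundary as CSV/JSON in a temp directory,
so results are deterministic functions of the data.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
from pathlib import Path

import pandas as pd

from .errors import AnalysisError, ConvergenceError

__all__ = ["lmer_available", "run_lmer_ladder"]

_R_SCRIPT = r"""
suppressMessages({ library(lme4); library(lmerTest); library(jsonlite) })
args <- commandArgs(trailingOnly = TRUE)
dat <- read.csv(args[1])
spec <- fromJSON(args[2], simplifyVector = TRUE)
out_path <- args[3]

fixed <- spec$fixed
sl <- list(participant = as.character(unlist(spec$participant_slopes)),
           item = as.character(unlist(spec$item_slopes)))

re_term <- function(unit, slopes, corr) {
  inner <- paste(c("1", slopes), collapse = " + ")
  op <- if (corr || length(slopes) == 0) "|" else "||"
  sprintf("(%s %s %s)", inner, op, unit)
}
build_formula <- function(sl, corr) {
  paste(fixed, "+", re_term("participant", sl$participant, corr),
        "+", re_term("item", sl$item, corr))
}

ctrl <- lmerControl(optimizer = "bobyqa", optCtrl = list(maxfun = 1e5))
fit_one <- function(f) {
  fit <- tryCatch(lmerTest::lmer(as.formula(f), data = dat, REML = TRUE, control = ctrl),
                  error = function(e) e)
  if (inherits(fit, "error"))
    return(list(ok = FALSE, error = conditionMessage(fit)))
  msgs <- unlist(fit@optinfo$conv$lme4$messages)
  list(ok = TRUE, fit = fit,
       converged = is.null(msgs) || length(msgs) == 0,
       singular = isSingular(fit, tol = 1e-4),
       messages = if (is.null(msgs)) character(0) else msgs)
}

slope_variances <- function(fit, sl) {
  vc <- as.data.frame(VarCorr(fit))
  out <- c()
  for (unit in names(sl)) for (term in sl[[unit]]) {
    rows <- vc[grepl(paste0("^", unit), vc$grp) & !is.na(vc$var1) &
               vc$var1 == term & is.na(vc$var2), ]
    v <- if (nrow(rows)) min(rows$vcov) else Inf
    out <- c(out, setNames(v, paste(unit, term, sep = "\r")))
  }
  out
}

trail <- list()
corr <- TRUE
best <- NULL; best_formula <- NULL
fallback <- NULL; fallback_formula <- NULL
last_fit <- NULL
repeat {
  f <- build_formula(sl, corr)
  res <- fit_one(f)
  status <- if (!res$ok) paste0("error: ", res$error)
            else if (!res$converged) "non-convergence"
            else if (res$singular) "singular"
            else "converged"
  trail[[length(trail) + 1]] <- list(formula = f, status = status)
  if (res$ok) last_fit <- res$fit
  if (res$ok && res$converged && !res$singular) {
    best <- res$fit; best_formula <- f; break
  }
  if (res$ok && res$converged && is.null(fallback)) {
    fallback <- res$fit; fallback_formula <- f
  }
  if (corr && length(c(sl$participant, sl$item)) > 0) { corr <- FALSE; next }
  if (length(c(sl$participant, sl$item)) == 0) break
  # interaction slopes go first, then the smallest estimated slope variance
  inter_p <- grep(":", sl$participant, value = TRUE)
  inter_i <- grep(":", sl$item, value = TRUE)
  if (length(inter_p)) { sl$participant <- setdiff(sl$participant, tail(inter_p, 1)); next }
  if (length(inter_i)) { sl$item <- setdiff(sl$item, tail(inter_i, 1)); next }
  drop_key <- NULL
  if (!is.null(last_fit)) {
    vars <- tryCatch(slope_variances(last_fit, sl), error = function(e) NULL)
    if (!is.null(vars) && length(vars)) drop_key <- names(vars)[which.min(vars)]
  }
  if (is.null(drop_key)) {
    unit <- if (length(sl$item)) "item" else "participant"
    drop_key <- paste(unit, tail(sl[[unit]], 1), sep = "\r")
  }
  parts <- strsplit(drop_key, "\r", fixed = TRUE)[[1]]
  sl[[parts[1]]] <- setdiff(sl[[parts[1]]], parts[2])
}

accepted_singular <- FALSE
if (is.null(best) && !is.null(fallback)) {
  best <- fallback; best_formula <- fallback_formula; accepted_singular <- TRUE
}
if (is.null(best)) {
  write(toJSON(list(converged = FALSE, trail = trail), auto_unbox = TRUE), out_path)
  quit(save = "no", status = 0)
}
ct <- summary(best)$coefficients
coefs <- lapply(rownames(ct), function(nm) list(
  term = nm,
  estimate = unname(ct[nm, "Estimate"]),
  se = unname(ct[nm, "Std. Error"]),
  df = unname(ct[nm, "df"]),
  t = unname(ct[nm, "t value"]),
  p = unname(ct[nm, "Pr(>|t|)"])))
write(toJSON(list(
  converged = TRUE,
  formula = best_formula,
  accepted_singular = accepted_singular,
  trail = trail,
  coefficients = coefs,
  n_obs = nobs(best),
  df_method = "Satterthwaite"
), auto_unbox = TRUE, digits = 12, na = "null"), out_path)
"""


def lmer_available() -> bool:
    """True when an Rscript with lme4/lmerTest is on the PATH."""
    return shutil.which("Rscript") is not None


def run_lmer_ladder(
    data: pd.DataFrame,
    fixed: str,
    participant_slopes: list[str],
    item_slopes: list[str],
    timeout_s: float = 600.0,
) -> dict:
    """Run the in-R simplification ladder and return the parsed result dict.

    Raises :class:`ConvergenceError` when no candidate converged at all and
    :class:`AnalysisError` on an R-level failure.
    """
    with tempfile.TemporaryDirectory(prefix="galatrack_lmer_") as tmp:
        tmp = Path(tmp)
        data.to_csv(tmp / "data.csv", index=False)
        (tmp / "spec.json").write_text(
            json.dumps(
                {
                    "fixed": fixed,
                    "participant_slopes": participant_slopes,
                    "item_slopes": item_slopes,
                }
            ),
            encoding="utf-8",
        )
        (tmp / "ladder.R").write_text(_R_SCRIPT, encoding="utf-8")
        proc = subprocess.run(
            [
                "Rscript",
                "--vanilla",
                str(tmp / "ladder.R"),
                str(tmp / "data.csv"),
                str(tmp / "spec.json"),
                str(tmp / "out.json"),
            ],
            capture_output=True,
            text=True,
            timeout=timeout_s,
        )
        if proc.returncode != 0 or not (tmp / "out.json").exists():
            raise AnalysisError(
                f"lme4 backend failed (exit {proc.returncode}): {proc.stderr[-2000:]}"
            )
        result = json.loads((tmp / "out.json").read_text(encoding="utf-8"))
    if not result.get("converged"):
        raise ConvergenceError(result.get("trail", []))
    return result
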