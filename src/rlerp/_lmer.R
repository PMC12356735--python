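# Mixed-model backend: fits lme4/lmerTest models for rlerp.mixedlm.
# Called as: Rscript _lmer.R <workdir>
# <workdir>/data.tsv  : model frame (numeric coded predictors + grouping id)
# <workdir>/spec.json : response, fixed RHS, ordered random structures to try,
#                       family, REML flag, optional contrast matrix, optional
#                       batch column
# Writes <workdir>/result.json.

suppressMessages({
  library(lme4)
  library(lmerTest)
  library(jsonlite)
})

args <- commandArgs(trailingOnly = TRUE)
workdir <- args[[1]]
spec <- fromJSON(file.path(workdir, "spec.json"), simplifyVector = TRUE)
dat <- read.delim(file.path(workdir, "data.tsv"), check.names = FALSE,
                  na.strings = c("NA", "n/a"))

group_var <- spec$group_var
dat[[group_var]] <- factor(dat[[group_var]])

make_formula <- function(response, fixed, random_terms, group_var) {
  re <- paste(c("1", random_terms), collapse = " + ")
  as.formula(paste0(response, " ~ ", fixed, " + (", re, " | ", group_var, ")"))
}

fit_once <- function(formula., data., family., reml) {
  warns <- character(0)
  handler <- function(w) {
    warns <<- c(warns, conditionMessage(w))
    invokeRestart("muffleWarning")
  }
  # keep every symbol of the model call resolvable from the global
  # environment: influence() and other post-hoc helpers re-evaluate it
  assign(".rlerp_data", data., envir = .GlobalEnv)
  assign(".rlerp_formula", formula., envir = .GlobalEnv)
  assign(".rlerp_reml", reml, envir = .GlobalEnv)
  model <- withCallingHandlers(
    tryCatch({
      if (family. == "gaussian") {
        lmerTest::lmer(.rlerp_formula, data = .rlerp_data, REML = .rlerp_reml,
                       control = lmerControl(optimizer = "bobyqa"))
      } else {
        lme4::glmer(.rlerp_formula, data = .rlerp_data, family = binomial(),
                    control = glmerControl(optimizer = "bobyqa"))
      }
    }, error = function(e) {
      warns <<- c(warns, paste0("ERROR: ", conditionMessage(e)))
      NULL
    }),
    warning = handler
  )
  conv_msgs <- character(0)
  if (!is.null(model)) {
    conv_msgs <- unlist(model@optinfo$conv$lme4$messages)
    if (is.null(conv_msgs)) conv_msgs <- character(0)
  }
  all_msgs <- c(warns, conv_msgs)
  failed <- is.null(model) ||
    any(grepl("converge|unable to evaluate|Hessian|failure|unidentifiable",
              all_msgs, ignore.case = TRUE))
  singular <- if (is.null(model)) FALSE else isSingular(model, tol = 1e-4)
  list(model = model, failed = failed, singular = singular, messages = all_msgs)
}

# Try random structures in the provided order (maximal first); a singular fit
# counts as a failure and triggers further reduction, except that the
# intercept-only structure is accepted even when singular (nothing left to
# delete).
fit_reduced <- function(data.) {
  structures <- spec$random_structures
  if (!is.list(structures)) structures <- list(structures)
  n <- length(structures)
  log <- list()
  last_ok <- NULL
  for (k in seq_len(n)) {
    terms <- unlist(structures[[k]])
    if (is.null(terms)) terms <- character(0)
    f <- make_formula(spec$response, spec$fixed, terms, group_var)
    res <- fit_once(f, data., spec$family, isTRUE(spec$reml))
    log[[k]] <- list(random_terms = as.list(terms), failed = res$failed,
                     singular = res$singular,
                     messages = as.list(res$messages))
    if (!res$failed) {
      last_ok <- list(res = res, terms = terms)
      if (!res$singular || length(terms) == 0) {
        return(list(fit = res, terms = terms, log = log, converged = TRUE))
      }
    }
  }
  if (!is.null(last_ok)) {
    return(list(fit = last_ok$res, terms = last_ok$terms, log = log,
                converged = TRUE))
  }
  list(fit = NULL, terms = NULL, log = log, converged = FALSE)
}

coef_table <- function(model, family.) {
  s <- summary(model)$coefficients
  if (family. == "gaussian") {
    data.frame(name = rownames(s), estimate = s[, "Estimate"],
               se = s[, "Std. Error"], df = s[, "df"],
               t = s[, "t value"], p = s[, "Pr(>|t|)"],
               stringsAsFactors = FALSE)
  } else {
    data.frame(name = rownames(s), estimate = s[, "Estimate"],
               se = s[, "Std. Error"], df = Inf,
               t = s[, "z value"], p = s[, "Pr(>|z|)"],
               stringsAsFactors = FALSE)
  }
}

extract_fit <- function(fr, diagnostics) {
  model <- fr$fit$model
  out <- list(
    converged = TRUE,
    singular = fr$fit$singular,
    random_terms = as.list(fr$terms),
    messages = as.list(fr$fit$messages),
    coefficients = coef_table(model, spec$family),
    nobs = nobs(model),
    sigma = sigma(model),
    log = fr$log
  )
  if (diagnostics) {
    out$vcov <- as.matrix(vcov(model))
    out$coef_names <- rownames(summary(model)$coefficients)
    out$residuals <- as.numeric(residuals(model))
    out$fitted <- as.numeric(fitted(model))
    out$hatvalues <- as.numeric(hatvalues(model))
    out$group_ids <- as.character(model.frame(model)[[group_var]])
  }
  if (isTRUE(spec$influence_groups)) {
    # delete-one-participant influence (exact refits)
    infl <- influence(model, groups = group_var)
    gc <- cooks.distance(infl)
    out$group_cooks <- as.numeric(gc)
    lv <- infl$deleted
    if (is.null(lv)) lv <- names(gc)
    out$group_levels <- as.character(lv)
  }
  if (!is.null(spec$contrasts) && spec$family == "gaussian") {
    L <- as.matrix(spec$contrasts$matrix)
    rows <- lapply(seq_len(nrow(L)), function(i) {
      ct <- lmerTest::contest1D(model, L[i, ], confint = FALSE)
      list(estimate = ct[["Estimate"]], se = ct[["Std. Error"]],
           df = ct[["df"]], t = ct[["t value"]], p = ct[["Pr(>|t|)"]])
    })
    out$contrast_results <- rows
    out$contrast_labels <- spec$contrasts$labels
  }
  out
}

diagnostics <- !isTRUE(spec$skip_diagnostics)

if (!is.null(spec$batch_col) && nchar(spec$batch_col) > 0) {
  reps <- unique(dat[[spec$batch_col]])
  fits <- list()
  for (i in seq_along(reps)) {
    sub <- dat[dat[[spec$batch_col]] == reps[[i]], , drop = FALSE]
    fitted <- fit_reduced(sub)
    if (fitted$converged) {
      f <- extract_fit(fitted, diagnostics = FALSE)
      f$log <- NULL
    } else {
      f <- list(converged = FALSE, log = fitted$log)
    }
    f$rep <- reps[[i]]
    fits[[i]] <- f
  }
  result <- list(batch = TRUE, fits = fits)
} else {
  fitted <- fit_reduced(dat)
  if (fitted$converged) {
    result <- extract_fit(fitted, diagnostics)
  } else {
    result <- list(converged = FALSE, log = fitted$log)
  }
}

write_json(result, file.path(workdir, "result.json"), auto_unbox = TRUE,
           digits = NA, na = "null", dataframe = "columns")
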