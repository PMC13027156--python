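#!/usr/bin/env Rscript
# Batch Gamma(sqrt-link) mixed-model fitting backend.
#
# Usage: Rscript _glmm_fit.R data.csv out.json control_label [--emmeans]
#
# data.csv columns: dataset, value, group, specimen, image, experiment.
# One glmmTMB fit per dataset id:
#   value ~ group + (1 | experiment) + (1 | experiment:specimen)
# with a random term dropped when its grouping factor has < 2 levels.
# Output: JSON list with per-dataset coefficients, covariance, random-effect
# SDs and convergence flags. With --emmeans, estimated marginal means and
# treatment-vs-control contrasts from the emmeans package are included
# (used as an independent cross-check of the Python-side EMM construction).

suppressMessages({
  library(glmmTMB)
  library(jsonlite)
})

args <- commandArgs(trailingOnly = TRUE)
data_path <- args[[1]]
out_path <- args[[2]]
control <- args[[3]]
want_emm <- "--emmeans" %in% args
if (want_emm) suppressMessages(library(emmeans))

d <- read.csv(data_path, stringsAsFactors = FALSE,
              colClasses = c(dataset = "character", group = "character",
                             specimen = "character", image = "character",
                             experiment = "character"))

fit_one <- function(di) {
  di$group <- relevel(factor(di$group), ref = control)
  di$spec_id <- interaction(di$experiment, di$specimen, drop = TRUE)
  re_terms <- character(0)
  if (length(unique(di$experiment)) >= 2) re_terms <- c(re_terms, "(1 | experiment)")
  if (nlevels(di$spec_id) >= 2) re_terms <- c(re_terms, "(1 | spec_id)")
  rhs <- paste(c("group", re_terms), collapse = " + ")
  form <- as.formula(paste("value ~", rhs))
  # start fixed effects at sqrt of the group means: the sqrt link makes the
  # likelihood sign-ambiguous in eta, and a data-derived start keeps the
  # optimizer on the positive branch
  mns <- tapply(di$value, di$group, mean)[levels(di$group)]
  beta0 <- sqrt(mns[[1]])
  beta_start <- c(beta0, sqrt(mns[-1]) - beta0)
  # weak regularization of random-effect SDs (density ~ sd^1.5, no upward
  # pull: gamma with shape 2.5 and near-zero rate), stabilizing small
  # designs where variance estimates would otherwise collapse to zero
  priors <- if (length(re_terms) > 0) {
    data.frame(prior = "gamma(1e6, 2.5)", class = "ranef")
  } else NULL
  fit <- try(suppressWarnings(
    glmmTMB(form, data = di, family = Gamma(link = "sqrt"),
            start = list(beta = beta_start), priors = priors)
  ), silent = TRUE)
  if (inherits(fit, "try-error")) {
    return(list(error = as.character(fit)))
  }
  # canonicalize: the Gamma likelihood is invariant under a global sign flip
  # of the linear predictor; if every group mean landed on the negative
  # branch, restart the optimizer from the mirrored optimum
  etas <- function(f) {
    b <- fixef(f)$cond
    c(b[[1]], b[[1]] + b[-1])
  }
  if (all(etas(fit) < 0)) {
    pf <- fit$fit$par
    mirrored <- list(beta = -fixef(fit)$cond,
                     theta = unname(pf[names(pf) == "theta"]),
                     betad = unname(pf[names(pf) == "betad"]))
    refit <- try(suppressWarnings(
      glmmTMB(form, data = di, family = Gamma(link = "sqrt"),
              start = mirrored, priors = priors)
    ), silent = TRUE)
    if (!inherits(refit, "try-error") && all(etas(refit) > 0)) fit <- refit
  }
  beta <- fixef(fit)$cond
  V <- as.matrix(vcov(fit)$cond)
  pdhess <- isTRUE(fit$sdr$pdHess)
  conv <- isTRUE(fit$fit$convergence == 0)
  vc <- VarCorr(fit)$cond
  re_sd <- vapply(vc, function(m) attr(m, "stddev")[[1]], numeric(1))
  out <- list(
    coef_names = names(beta),
    beta = unname(beta),
    vcov = V,
    converged = conv && pdhess,
    random_terms = re_terms,
    re_sd = as.list(re_sd),
    sigma = sigma(fit)
  )
  if (want_emm) {
    emm <- emmeans(fit, "group")
    emm_resp <- summary(emm, type = "response")
    ctr <- summary(contrast(emm, method = "trt.vs.ctrl", ref = control),
                   adjust = "none")
    out$emmeans <- list(
      group = as.character(emm_resp$group),
      response = emm_resp$response,
      contrast_names = as.character(ctr$contrast),
      contrast_estimate = ctr$estimate,
      contrast_p = ctr$p.value
    )
  }
  out
}

results <- list()
for (ds in unique(d$dataset)) {
  results[[ds]] <- fit_one(d[d$dataset == ds, , drop = FALSE])
}
write_json(results, out_path, digits = NA, auto_unbox = TRUE)
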