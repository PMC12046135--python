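# Penalized thin-plate GAM fits (REML) with basis-size selection.
# Called as: Rscript gam_fit.R data.csv spec.json out.json
# The CSV may stack several datasets distinguished by a dataset id column;
# each is fitted independently and one result object returned per dataset.

suppressMessages({
  library(mgcv)
  library(jsonlite)
})

args <- commandArgs(trailingOnly = TRUE)
dat <- read.csv(args[1], stringsAsFactors = FALSE, check.names = FALSE)
spec <- fromJSON(args[2])

exposure <- spec$exposure
outcome <- spec$outcome
covs <- spec$covariates
if (is.null(covs)) covs <- character(0)
factor_covs <- spec$factor_covariates
if (is.null(factor_covs)) factor_covs <- character(0)
k_grid <- as.integer(spec$k_grid)
n_grid <- if (is.null(spec$n_grid)) 100L else as.integer(spec$n_grid)
want_curve <- if (is.null(spec$curve)) TRUE else isTRUE(spec$curve)
seed <- if (is.null(spec$seed)) 0L else as.integer(spec$seed)

kcheck <- tryCatch(get("k.check", asNamespace("mgcv")), error = function(e) NULL)

fit_one <- function(d) {
  for (fc in factor_covs) d[[fc]] <- factor(d[[fc]])
  covstr <- if (length(covs) > 0) paste("+", paste(covs, collapse = " + ")) else ""
  fit <- NULL
  used_k <- NA
  for (k in k_grid) {
    f <- as.formula(paste0(outcome, " ~ s(", exposure, ", k=", k, ", bs='tp')", covstr))
    cand <- tryCatch(gam(f, data = d, method = "REML"), error = function(e) NULL)
    if (is.null(cand)) next
    fit <- cand
    used_k <- k
    if (length(k_grid) == 1 || is.null(kcheck)) break
    kc <- tryCatch(kcheck(cand, subsample = 5000, n.rep = 200), error = function(e) NULL)
    if (is.null(kc)) break
    pv <- kc[1, "p-value"]
    if (is.na(pv) || pv > 0.05) break  # basis adequate
  }
  if (is.null(fit)) stop("GAM fit failed for every k in the grid")

  sm <- summary(fit)
  st <- sm$s.table
  pt <- sm$p.table
  parametric <- data.frame(
    term = rownames(pt), estimate = pt[, 1], se = pt[, 2],
    stat = pt[, 3], p = pt[, 4], row.names = NULL
  )

  out <- list(
    k = used_k,
    edf = unname(st[1, "edf"]),
    ref_df = unname(st[1, "Ref.df"]),
    f_stat = unname(st[1, 3]),
    p_value = unname(st[1, 4]),
    sp = unname(fit$sp[1]),
    r_sq = unname(sm$r.sq),
    n = nrow(d),
    parametric = parametric
  )

  if (want_curve) {
    xs <- seq(min(d[[exposure]]), max(d[[exposure]]), length.out = n_grid)
    nd <- data.frame(x = xs)
    names(nd) <- exposure
    for (cv in covs) {
      col <- d[[cv]]
      if (is.factor(col)) {
        nd[[cv]] <- factor(names(sort(table(col), decreasing = TRUE))[1], levels = levels(col))
      } else {
        nd[[cv]] <- mean(col)
      }
    }
    pr <- predict(fit, newdata = nd, se.fit = TRUE)
    out$curve <- data.frame(
      x = xs, fit = as.numeric(pr$fit),
      lo = as.numeric(pr$fit - 1.96 * pr$se.fit),
      hi = as.numeric(pr$fit + 1.96 * pr$se.fit)
    )
  }
  out
}

set.seed(seed)
if (!is.null(spec$dataset_col) && spec$dataset_col %in% names(dat)) {
  ids <- unique(dat[[spec$dataset_col]])
  results <- lapply(ids, function(i) {
    r <- tryCatch(fit_one(dat[dat[[spec$dataset_col]] == i, , drop = FALSE]),
                  error = function(e) list(error = conditionMessage(e)))
    r$dataset <- i
    r
  })
} else {
  results <- list(fit_one(dat))
}

writeLines(toJSON(results, auto_unbox = TRUE, digits = 12, na = "null"), args[3])
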