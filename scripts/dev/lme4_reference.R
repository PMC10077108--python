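# Reference REML fit of the eGFR mixed model with lme4, frozen into
# tests/data/lme4_reference.json for the fitter oracle test.
# Model: egfr ~ predictors * time + (1 + time | subject) + (1 | country), REML.
suppressMessages({
  library(lme4)
  library(jsonlite)
})

base <- read.csv("tests/data/synthetic_two_country_baseline.csv")
vis <- read.csv("tests/data/synthetic_two_country_visits.csv")
d <- merge(vis, base[, setdiff(names(base), "country")], by = "subject_id")
d$time <- d$time_years

preds <- c("age", "sex", "bmi", "smoking_ever", "hba1c", "hemoglobin",
           "cholesterol", "map", "log2_uacr", "med_glucose", "med_bp",
           "med_lipid")
rhs <- paste(c(preds, "time", paste0(preds, ":time")), collapse = " + ")
form <- as.formula(paste("egfr ~", rhs,
                         "+ (1 + time | subject_id) + (1 | country)"))

ctrl <- lmerControl(optimizer = "bobyqa",
                    optCtrl = list(rhoend = 1e-12, maxfun = 100000))
fit <- lmer(form, data = d, REML = TRUE, control = ctrl)

vc <- VarCorr(fit)
G <- as.matrix(Matrix::bdiag(vc$subject_id))
tau2 <- as.numeric(vc$country[1, 1])
sigma2 <- sigma(fit)^2
beta <- fixef(fit)
# map lme4 term names onto the package's column names
names(beta) <- sub("^\\(Intercept\\)$", "intercept", names(beta))

out <- list(
  loglik = as.numeric(logLik(fit)),
  reml_criterion = REMLcrit(fit),
  beta = as.list(beta),
  G = unname(G),
  tau2 = tau2,
  sigma2 = sigma2,
  n_obs = nrow(d),
  converged = length(fit@optinfo$conv$lme4) == 0
)
write_json(out, "tests/data/lme4_reference.json", digits = 12, auto_unbox = TRUE)
cat("loglik:", out$loglik, " sigma2:", sigma2, " tau2:", tau2, "\n")
print(G)
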