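{"loglik":-1996.385934545319,"reml_criterion":3992.771869090639,"beta":{"intercept":95.778334038951,"age":-0.2711292596199,"sex":0.495907708021,"bmi":-0.3956241216788,"smoking_ever":-6.416820935358,"hba1c":-0.1324364632458,"hemoglobin":3.091836558151,"cholesterol":-0.03850605461989,"map":-0.006007133483731,"log2_uacr":-1.901473584898,"med_glucose":-5.178591723625,"med_bp":-1.343613479051,"med_lipid":-0.2618222067173,"time":5.116725640055,"age:time":-0.04302277746011,"sex:time":-0.1250269705988,"bmi:time":-0.009793272047925,"smoking_ever:time":1.72700557565,"hba1c:time":-0.002807724798443,"hemoglobin:time":-0.2124360386697,"cholesterol:time":0.002401119395974,"map:time":-0.01410160412295,"log2_uacr:time":0.09050670471845,"med_glucose:time":1.128936949792,"med_bp:time":-1.66018265745,"med_lipid:time":-0.0346581748565},"G":[[229.812269326956,-7.245640270067],[-7.245640270067,3.67725571525]],"tau2":227.955478623796,"sigma2":35.402086235241,"n_obs":554,"converged":true}
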