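canonical,synonyms,classes
fentanyl,n-phenyl-n-[1-(2-phenylethyl)-4-piperidinyl]-propanamide|fentanyl citrate,opioid
acetyl fentanyl,acetylfentanyl,opioid
carfentanil,carfentanyl,opioid
4-fluorobutyrfentanyl,4-fbf|4-fluorobutyryl fentanyl,opioid
4-fluoroisobutyryl fentanyl,4-fibf|4-fluoroisobutyrylfentanyl,opioid
heroin,diacetylmorphine|diamorphine,opioid
morphine,,opioid
codeine,,opioid
oxycodone,oxycontin|percocet,opioid
oxymorphone,opana,opioid
hydrocodone,vicodin,opioid
hydromorphone,dilaudid,opioid
methadone,,opioid
buprenorphine,suboxone,opioid
tramadol,,opioid
u-47700,u47700,opioid
mitragynine,kratom,opioid|stimulant
cocaine,coke|benzoylmethylecgonine,stimulant
methamphetamine,meth|crystal meth,stimulant
amphetamine,adderall,stimulant
mdma,ecstasy|3-4-methylenedioxymethamphetamine|molly,stimulant
methylphenidate,ritalin,stimulant
cathinone,bath salts,stimulant
ethanol,alcohol|ethyl alcohol|ethanolism,alcohol
alprazolam,xanax,benzodiazepine
diazepam,valium,benzodiazepine
clonazepam,klonopin,benzodiazepine
lorazepam,ativan,benzodiazepine
temazepam,restoril,benzodiazepine
etizolam,,benzodiazepine
flualprazolam,,benzodiazepine
amitriptyline,elavil,anti-depressant
nortriptyline,pamelor,anti-depressant
sertraline,zoloft,anti-depressant
fluoxetine,prozac,anti-depressant
citalopram,celexa,anti-depressant
trazodone,,anti-depressant
bupropion,wellbutrin,anti-depressant
venlafaxine,effexor,anti-depressant
xylazine,,other
gabapentin,neurontin,other
diphenhydramine,benadryl,other
ketamine,,other
acetaminophen,paracetamol|tylenol,other
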