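BEGIN IONS
TITLE=1
PEPMASS=625.14233
CHARGE=1-
RTINSECONDS=318
301 30
343 5
462 20
463 100
505 5
END IONS
BEGIN IONS
TITLE=2
PEPMASS=771.20038
CHARGE=1-
RTINSECONDS=344.4
301 5
463 10
609 100
END IONS
BEGIN IONS
TITLE=3
PEPMASS=625.14172
CHARGE=1-
RTINSECONDS=351
255 10
271 20
300 100
301 50
343 10
445 50
463 15
505 15
END IONS
BEGIN IONS
TITLE=4
PEPMASS=533.09454
CHARGE=1-
RTINSECONDS=353.4
285 5
489 100
END IONS
BEGIN IONS
TITLE=5
PEPMASS=609.14636
CHARGE=1-
RTINSECONDS=354
285 100
327 5
446 50
447 70
489 10
581 10
END IONS
BEGIN IONS
TITLE=6
PEPMASS=785.21509
CHARGE=1-
RTINSECONDS=354.6
315 5
477 10
623 100
END IONS
BEGIN IONS
TITLE=7
PEPMASS=639.15717
CHARGE=1-
RTINSECONDS=357.6
300 10
315 100
357 5
476 20
477 40
END IONS
BEGIN IONS
TITLE=8
PEPMASS=771.20056
CHARGE=1-
RTINSECONDS=358.8
300 50
301 45
409 10
427 10
445 10
573 20
591 40
609 30
625 100
753 10
END IONS
BEGIN IONS
TITLE=9
PEPMASS=595.13098
CHARGE=1-
RTINSECONDS=360
255 10
271 20
300 100
301 45
445 15
463 10
475 10
END IONS
BEGIN IONS
TITLE=10
PEPMASS=639.15784
CHARGE=1-
RTINSECONDS=361.2
299 60
300 50
314 50
315 100
444 30
459 65
477 20
491 10
519 15
624 20
END IONS
BEGIN IONS
TITLE=11
PEPMASS=609.14642
CHARGE=1-
RTINSECONDS=362.4
255 10
271 15
285 5
300 100
301 20
343 5
429 10
445 20
463 10
489 15
END IONS
BEGIN IONS
TITLE=12
PEPMASS=609.14697
CHARGE=1-
RTINSECONDS=364.2
255 15
284 80
285 90
327 10
429 100
447 10
489 5
END IONS
BEGIN IONS
TITLE=13
PEPMASS=755.20471
CHARGE=1-
RTINSECONDS=371.4
255 25
284 70
285 90
429 20
575 85
593 90
609 100
END IONS
BEGIN IONS
TITLE=14
PEPMASS=623.16211
CHARGE=1-
RTINSECONDS=373.2
299 65
300 10
314 100
315 15
327 10
444 10
459 30
477 10
503 10
608 10
END IONS
BEGIN IONS
TITLE=15
PEPMASS=609.14679
CHARGE=1-
RTINSECONDS=374.4
255 5
271 10
300 20
301 100
343 5
END IONS
BEGIN IONS
TITLE=16
PEPMASS=609.14716
CHARGE=1-
RTINSECONDS=375.6
299 30
300 20
314 90
315 100
357 10
459 50
477 5
489 5
577 15
END IONS
BEGIN IONS
TITLE=17
PEPMASS=593.15161
CHARGE=1-
RTINSECONDS=376.8
255 20
284 100
285 40
327 5
429 50
447 10
473 5
END IONS
BEGIN IONS
TITLE=18
PEPMASS=579.13678
CHARGE=1-
RTINSECONDS=378
255 30
284 100
285 75
327 10
429 60
447 20
459 5
END IONS
BEGIN IONS
TITLE=19
PEPMASS=623.16248
CHARGE=1-
RTINSECONDS=380.4
299 25
300 10
314 100
315 35
357 5
459 25
477 10
503 10
591 5
END IONS
BEGIN IONS
TITLE=20
PEPMASS=463.08951
CHARGE=1-
RTINSECONDS=383.4
300 20
301 100
END IONS
BEGIN IONS
TITLE=21
PEPMASS=609.14697
CHARGE=1-
RTINSECONDS=385.8
255 5
271 10
300 20
315 100
END IONS
BEGIN IONS
TITLE=22
PEPMASS=549.08923
CHARGE=1-
RTINSECONDS=392.4
301 5
505 100
END IONS
BEGIN IONS
TITLE=23
PEPMASS=623.16272
CHARGE=1-
RTINSECONDS=394.2
255 5
271 10
300 20
314 10
315 100
END IONS
BEGIN IONS
TITLE=24
PEPMASS=477.10477
CHARGE=1-
RTINSECONDS=399
314 20
315 100
END IONS
BEGIN IONS
TITLE=25
PEPMASS=447.09424
CHARGE=1-
RTINSECONDS=402
255 10
284 100
285 80
327 20
END IONS
BEGIN IONS
TITLE=26
PEPMASS=477.10437
CHARGE=1-
RTINSECONDS=406.8
314 100
315 30
357 15
449 5
END IONS
BEGIN IONS
TITLE=27
PEPMASS=563.10486
CHARGE=1-
RTINSECONDS=411.6
315 5
519 100
END IONS
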