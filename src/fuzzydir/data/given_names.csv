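name,count
james,3318
john,3271
robert,3143
michael,2629
william,2451
david,2363
richard,1703
charles,1523
joseph,1404
thomas,1380
mary,2629
patricia,1073
linda,1035
barbara,980
elizabeth,937
jennifer,932
maria,828
susan,794
margaret,768
dorothy,727
christopher,1035
daniel,974
paul,948
mark,938
donald,931
george,927
kenneth,826
steven,780
edward,779
brian,736
ronald,725
anthony,721
kevin,671
jason,660
matthew,657
gary,650
timothy,640
jose,613
larry,598
jeffrey,591
frank,581
scott,546
eric,544
stephen,540
andrew,537
raymond,488
gregory,441
joshua,435
jerry,432
dennis,415
walter,399
patrick,389
peter,381
harold,371
douglas,367
henry,365
carl,349
arthur,335
ryan,328
roger,322
joe,316
juan,316
jack,315
albert,314
jonathan,313
justin,311
terry,311
gerald,305
keith,294
samuel,292
willie,290
ralph,282
lawrence,282
nicholas,275
roy,273
benjamin,268
bruce,261
brandon,260
adam,259
harry,251
fred,249
wayne,249
billy,248
steve,246
louis,243
jeremy,242
aaron,240
randy,232
howard,230
eugene,229
carlos,229
russell,224
bobby,223
victor,222
martin,216
ernest,215
phillip,214
todd,213
jesse,209
craig,206
alan,202
philip,199
shawn,189
clarence,177
sean,175
lisa,704
nancy,669
karen,667
betty,666
helen,663
sandra,629
donna,583
carol,573
ruth,562
sharon,522
michelle,519
laura,510
sarah,508
kimberly,504
deborah,494
jessica,490
shirley,482
cynthia,469
angela,468
melissa,462
brenda,455
amy,451
anna,440
rebecca,430
virginia,430
kathleen,424
pamela,416
martha,395
debra,395
amanda,391
stephanie,391
carolyn,385
christine,382
marie,379
janet,379
catherine,373
frances,370
ann,364
joyce,364
diane,359
alice,357
julie,348
heather,337
teresa,336
doris,335
gloria,334
evelyn,322
jean,315
cheryl,314
mildred,312
katherine,311
joan,306
ashley,303
judith,297
rose,296
janice,285
kelly,283
nicole,281
judy,276
christina,275
kathy,272
theresa,271
beverly,267
denise,266
tammy,258
irene,253
jane,250
lori,248
rachel,242
marilyn,241
andrea,236
kathryn,235
louise,232
sara,230
anne,228
jacqueline,228
wanda,226
bonnie,223
julia,223
ruby,221
lois,220
tina,219
phyllis,219
norma,213
paula,210
diana,209
annie,209
lillian,206
emily,205
robin,205
rita,200
abigail,160
victoria,159
jonah,80
caesar,20
roderick,60
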